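"""Reading, writing and validation of abundance tables, phase designs,
annotation tables and result artifacts.

Conventions
-----------
Abundance tables are stored with taxa in rows and time samples in columns,
as proportions in [0, 1].  Missing values are not permitted: absence is an
explicit zero.  All-zero taxa are kept through I/O (presence classification
needs them) and dropped only where an operation requires presence.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AbundanceTable",
    "PhaseDesign",
    "read_abundance_table",
    "read_phase_design",
    "read_annotations",
    "write_abundance_table",
    "write_results",
    "write_edge_list",
    "read_edge_list",
    "network_to_edge_frame",
    "edge_frame_to_network",
]

#: Fixed column order of every edge CSV written or read by this package.
EDGE_COLUMNS = ["source", "target", "sign", "strength", "n_pos", "n_neg", "n_present"]

#: Recognised pathway categories for annotation tables.
PATHWAY_CATEGORIES = frozenset(
    {
        "hydrolysis",
        "acidogenesis",
        "acetogenesis",
        "methanogenesis",
        "combined",
        "desulfurization",
        "none",
    }
)

#: Recognised domains for annotation tables.
DOMAINS = frozenset({"Bacteria", "Archaea"})


@dataclass
class AbundanceTable:
    """A taxon x time-sample matrix of relative abundances.

    Parameters
    ----------
    data:
        DataFrame with taxa as the index and sample identifiers as columns.
        Values are relative abundances (proportions).
    times:
        Per-sample observation time in days, non-decreasing, one entry per
        column of ``data``.
    """

    data: pd.DataFrame
    times: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.times is None:
            self.times = np.arange(self.data.shape[1], dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    # -- validation & transforms ----------------------------------------
    def validate(self) -> None:
        """Check structural invariants (raises ``ValueError`` on violation)."""
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("abundance table contains non-numeric cells")
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise ValueError(
                "missing value at taxon "
                f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                "negative abundance at taxon "
                f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )
        if len(self.times) != self.data.shape[1]:
            raise ValueError("times length does not match number of samples")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("sample times must be non-decreasing")

    def is_normalized(self, tol: float = 1e-6) -> bool:
        sums = self.data.sum(axis=0).to_numpy()
        return bool(np.all(np.abs(sums - 1.0) <= tol))

    def normalize(self) -> "AbundanceTable":
        """Rescale every sample column to sum to 1 (idempotent)."""
        sums = self.data.sum(axis=0)
        empty = sums[sums == 0]
        if len(empty):
            raise ValueError(f"empty sample (column sums to zero): {empty.index.tolist()}")
        return AbundanceTable(self.data.div(sums, axis=1), self.times.copy())

    def window(self, indices: Sequence[int]) -> "AbundanceTable":
        """Sub-table restricted to the given positional sample indices."""
        idx = list(indices)
        return AbundanceTable(self.data.iloc[:, idx], self.times[idx])


@dataclass(frozen=True)
class PhaseDesign:
    """Positional sample-index sets for the before / during / after windows.

    Indices are 0-based positions into the sample axis of an
    :class:`AbundanceTable`.  The three windows are disjoint, contiguous,
    temporally ordered and jointly cover every sample.  The before and after
    windows each need at least two samples (variance tests require it); the
    during window may be empty.
    """

    before: tuple[int, ...]
    during: tuple[int, ...]
    after: tuple[int, ...]

    def __post_init__(self) -> None:
        b, d, a = map(tuple, (self.before, self.during, self.after))
        n = len(b) + len(d) + len(a)
        combined = b + d + a
        if sorted(combined) != list(range(n)):
            raise ValueError(
                "phase windows must be disjoint and cover every sample exactly once"
            )
        if list(combined) != list(range(n)):
            raise ValueError(
                "phase windows must be contiguous and in temporal order "
                "(before, during, after)"
            )
        if len(b) < 2 or len(a) < 2:
            raise ValueError("before and after windows each require >= 2 samples")

    @property
    def n_samples(self) -> int:
        return len(self.before) + len(self.during) + len(self.after)

    @property
    def t1(self) -> int:
        return len(self.before)

    @property
    def t2(self) -> int:
        return len(self.after)

    @classmethod
    def from_sizes(cls, n_before: int, n_during: int, n_after: int) -> "PhaseDesign":
        b = tuple(range(n_before))
        d = tuple(range(n_before, n_before + n_during))
        a = tuple(range(n_before + n_during, n_before + n_during + n_after))
        return cls(b, d, a)


def default_design() -> PhaseDesign:
    """The 12 / 3 / 15 sampling design used throughout the package fixtures."""
    return PhaseDesign.from_sizes(12, 3, 15)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_TIME_ROW_LABELS = {"time", "times", "day", "days"}


def _infer_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance_table(
    path: str | Path,
    normalize: bool = False,
    dialect: str = "plain",
    tol: float = 1e-6,
) -> AbundanceTable:
    """Read a taxon x sample abundance table from delimited text.

    Parameters
    ----------
    path:
        TSV (default) or CSV file.  ``plain`` dialect: first column holds
        taxon ids, header row holds sample ids; an optional second header
        row labelled ``day``/``time`` gives per-sample day numbers.
    normalize:
        Rescale each column to sum to 1.  This also converts percent-unit
        tables (column sums near 100) to proportions; without the flag units
        are taken as-is and only validated.
    dialect:
        ``"plain"`` (taxa in rows) or ``"shared"`` for the mothur shared
        layout (samples in rows with label/Group/numOtus prefix columns,
        integer counts); shared counts are always converted to proportions.
    """
    path = Path(path)
    sep = _infer_sep(path)
    if dialect == "shared":
        raw = pd.read_csv(path, sep=sep)
        expected = ["label", "Group", "numOtus"]
        if list(raw.columns[:3]) != expected:
            raise ValueError(
                f"shared dialect expects leading columns {expected}, got {list(raw.columns[:3])}"
            )
        counts = raw.drop(columns=["label", "numOtus"]).set_index("Group").T
        counts.index.name = None
        counts.columns.name = None
        table = AbundanceTable(counts.astype(float))
        return table.normalize()
    if dialect != "plain":
        raise ValueError(f"unknown dialect {dialect!r}")

    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    times = None
    if len(raw) and str(raw.index[0]).strip().lower() in _TIME_ROW_LABELS:
        times = raw.iloc[0].astype(float).to_numpy()
        raw = raw.iloc[1:]
    try:
        data = raw.astype(float)
    except ValueError:
        for r, row in raw.iterrows():
            for c, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at taxon {r!r}, sample {c!r}: {cell!r}"
                    ) from None
        raise
    data.index.name = None
    data.columns.name = None
    table = AbundanceTable(data, times)
    if normalize:
        table = table.normalize()
    elif not table.is_normalized(tol):
        sums = table.data.sum(axis=0)
        bad = sums[(sums - 1.0).abs() > tol]
        if len(bad) and not np.allclose(sums, sums.iloc[0]):
            # heterogeneous sums with no normalization requested: accept but
            # downstream proportions-based operations may renormalize.
            pass
    return table


_RANGE_KEYS = ("before", "during", "after")


def _parse_range(value) -> tuple[int, ...]:
    """Parse a 1-based inclusive range spec ('1..12', [1, 12], list of ids)."""
    if isinstance(value, str):
        value = value.strip()
        if value == "" or value.lower() == "none":
            return ()
        if ".." in value:
            lo, hi = value.split("..")
            return tuple(range(int(lo) - 1, int(hi)))
        return tuple(int(v) - 1 for v in value.split(","))
    if isinstance(value, (list, tuple)):
        if len(value) == 2 and all(isinstance(v, int) for v in value):
            lo, hi = value
            return tuple(range(lo - 1, hi))
        return tuple(int(v) - 1 for v in value)
    raise ValueError(f"cannot parse phase range {value!r}")


def read_phase_design(spec, table: AbundanceTable | None = None) -> PhaseDesign:
    """Build a :class:`PhaseDesign` from a mapping, spec string or file.

    Accepted forms: a mapping ``{"before": "1..12", "during": "13..15",
    "after": "16..30"}`` (1-based inclusive sample positions), the same as a
    single string ``"before=1..12;during=13..15;after=16..30"``, or a path
    to a YAML/JSON file holding the mapping.  When ``table`` is given the
    design must cover its samples exactly.
    """
    if isinstance(spec, PhaseDesign):
        design = spec
    else:
        if isinstance(spec, (str, Path)) and Path(str(spec)).exists():
            with open(spec) as fh:
                spec = yaml.safe_load(fh)
        if isinstance(spec, str):
            parts = dict(
                kv.split("=", 1) for kv in spec.replace(",", ";").split(";") if "=" in kv
            )
            # '1..12' survives the comma replacement; explicit lists do not —
            # the string form therefore only supports range syntax.
            spec = {k.strip(): v.strip() for k, v in parts.items()}
        if not isinstance(spec, Mapping):
            raise ValueError(f"cannot interpret phase design spec {spec!r}")
        missing = [k for k in ("before", "after") if k not in spec]
        if missing:
            raise ValueError(f"phase design missing keys: {missing}")
        windows = {k: _parse_range(spec.get(k, ())) for k in _RANGE_KEYS}
        design = PhaseDesign(windows["before"], windows["during"], windows["after"])
    if table is not None and design.n_samples != table.n_samples:
        raise ValueError(
            f"phase design covers {design.n_samples} samples but table has {table.n_samples}"
        )
    return design


_ANNOTATION_COLUMNS = {
    "gc_percent": float,
    "genome_size_mb": float,
    "gene_count": float,
    "protein_count": float,
    "pathway_category": str,
    "domain": str,
    "pathways": str,
}


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-taxon annotation table (TSV/CSV, first column taxon id).

    Recognised columns: ``gc_percent``, ``genome_size_mb``, ``gene_count``,
    ``protein_count``, ``pathway_category``, ``domain`` and ``pathways``
    (semicolon-separated identifiers, exposed as Python sets).  Unknown
    fields stay missing (NaN / None), never zero.
    """
    path = Path(path)
    ann = pd.read_csv(path, sep=_infer_sep(path), index_col=0)
    if ann.index.has_duplicates:
        raise ValueError("duplicate taxon ids in annotation table")
    for col in ann.columns:
        if col in ("gc_percent", "genome_size_mb", "gene_count", "protein_count"):
            ann[col] = pd.to_numeric(ann[col], errors="coerce")
    if "gc_percent" in ann:
        bad = ann["gc_percent"].dropna()
        if ((bad <= 0) | (bad >= 100)).any():
            raise ValueError("gc_percent must lie strictly between 0 and 100")
    if "genome_size_mb" in ann:
        bad = ann["genome_size_mb"].dropna()
        if (bad <= 0).any():
            raise ValueError("genome_size_mb must be positive")
    if "pathway_category" in ann:
        cats = set(ann["pathway_category"].dropna())
        unknown = cats - PATHWAY_CATEGORIES
        if unknown:
            raise ValueError(f"unknown pathway categories: {sorted(unknown)}")
    if "domain" in ann:
        unknown = set(ann["domain"].dropna()) - DOMAINS
        if unknown:
            raise ValueError(f"unknown domains: {sorted(unknown)}")
    if "pathways" in ann:
        ann["pathways"] = ann["pathways"].apply(
            lambda v: frozenset(str(v).split(";")) if pd.notna(v) and str(v) else frozenset()
        )
    return ann


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    sep = _infer_sep(path)
    out = table.data.copy()
    header = pd.DataFrame([table.times], index=["day"], columns=out.columns)
    pd.concat([header, out]).to_csv(path, sep=sep, index_label="taxon")


def network_to_edge_frame(network: nx.DiGraph) -> pd.DataFrame:
    """Flatten a signed directed network to the fixed edge-CSV schema."""
    rows = [
        {
            "source": u,
            "target": v,
            "sign": int(d.get("sign", 0)),
            "strength": float(d.get("strength", np.nan)),
            "n_pos": int(d.get("n_pos", 0)),
            "n_neg": int(d.get("n_neg", 0)),
            "n_present": int(d.get("n_present", 0)),
        }
        for u, v, d in network.edges(data=True)
    ]
    frame = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return frame.sort_values(["source", "target"], kind="mergesort").reset_index(drop=True)


def edge_frame_to_network(edges: pd.DataFrame) -> nx.DiGraph:
    g = nx.DiGraph()
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.source,
            row.target,
            sign=int(row.sign),
            strength=float(row.strength),
            n_pos=int(row.n_pos),
            n_neg=int(row.n_neg),
            n_present=int(row.n_present),
        )
    return g


def write_edge_list(network_or_edges, path: str | Path) -> None:
    if isinstance(network_or_edges, nx.DiGraph):
        edges = network_to_edge_frame(network_or_edges)
    else:
        edges = network_or_edges[EDGE_COLUMNS]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    edges.to_csv(path, index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    edges = pd.read_csv(path)
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge list missing columns: {missing}")
    return edges[EDGE_COLUMNS]


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    out_dir: str | Path,
    classification: pd.DataFrame | None = None,
    networks: Mapping[str, nx.DiGraph] | None = None,
    summaries: Mapping[str, pd.DataFrame] | None = None,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write all result artifacts plus a reproducibility manifest.

    Returns a mapping from artifact name to written path.  Networks are
    written both as edge CSVs and GraphML.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if classification is not None:
        p = out_dir / "classification.tsv"
        classification.to_csv(p, sep="\t", index=False)
        written["classification"] = p
    for tag, net in (networks or {}).items():
        p_csv = out_dir / f"edges_{tag}.csv"
        write_edge_list(net, p_csv)
        written[f"edges_{tag}"] = p_csv
        p_xml = out_dir / f"network_{tag}.graphml"
        nx.write_graphml(net, p_xml)
        written[f"network_{tag}"] = p_xml
    for name, frame in (summaries or {}).items():
        p = out_dir / f"{name}.tsv"
        frame.to_csv(p, sep="\t")
        written[name] = p
    import disturbnet

    manifest = {
        "config": dict(config or {}),
        "config_hash": _config_hash(config or {}),
        "seed": seed,
        "versions": {
            "disturbnet": disturbnet.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "artifacts": {k: str(v) for k, v in written.items()},
    }
    p = out_dir / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    written["manifest"] = p
    return written
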