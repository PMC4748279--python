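"""Readers and writers for every table the pipeline consumes or emits.

All tables are plain TSV.  Networks are exchanged as edge-list TSV plus
GraphML (which carries the node type attribute needed for a lossless
round trip).  Sample metadata travels in a separate TSV keyed by sample
id.  Every reader validates its invariants and reports the first
offending line of a malformed file.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .errors import FormatError

logger = logging.getLogger(__name__)

RNA_TYPES = ("gene", "lincRNA")


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-seq sample of the stress time course."""

    sample_id: str
    tissue: str
    condition: str
    timepoint: str
    hours: float
    replicate: int

    def __post_init__(self):
        if self.hours <= 0:
            raise FormatError(
                f"sample {self.sample_id!r}: hour-equivalent must be > 0, got {self.hours}")
        if self.replicate < 1:
            raise FormatError(
                f"sample {self.sample_id!r}: replicate must be >= 1, got {self.replicate}")


@dataclass
class ExpressionMatrix:
    """RNA x sample RPKM matrix with per-sample metadata.

    ``values`` is indexed by RNA id with one column per sample id, in the
    order of ``samples``.  ``rna_types`` maps every RNA id to ``gene`` or
    ``lincRNA``.
    """

    values: pd.DataFrame
    rna_types: pd.Series
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        self.values.index.name = "rna_id"
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate RNA id {dup!r}")
        if (self.values.to_numpy() < 0).any():
            col = self.values.columns[(self.values < 0).any(axis=0)][0]
            row = self.values.index[(self.values[col] < 0)][0]
            raise FormatError(f"negative RPKM at RNA {row!r}, sample {col!r}")
        ids = {s.sample_id for s in self.samples}
        if len(ids) != len(self.samples):
            raise FormatError("duplicate sample ids in metadata")
        unknown = [c for c in self.values.columns if c not in ids]
        if unknown:
            raise FormatError(f"sample column {unknown[0]!r} has no metadata")
        missing = self.rna_types.reindex(self.values.index)
        if missing.isna().any():
            raise FormatError(
                f"RNA {missing.index[missing.isna()][0]!r} has no declared type")
        bad = ~self.rna_types.isin(RNA_TYPES)
        if bad.any():
            raise FormatError(
                f"RNA {self.rna_types.index[bad][0]!r} has unknown type "
                f"{self.rna_types[bad].iloc[0]!r}")

    @property
    def rna_ids(self) -> list[str]:
        return list(self.values.index)

    def sample_meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def select_samples(self, predicate: Callable[[SampleMeta], bool]) -> "ExpressionMatrix":
        keep = [s for s in self.samples if predicate(s)]
        cols = [s.sample_id for s in keep]
        return ExpressionMatrix(self.values[cols].copy(), self.rna_types.copy(), keep)

    def lincrna_ids(self) -> list[str]:
        return [r for r in self.values.index if self.rna_types[r] == "lincRNA"]

    def gene_ids(self) -> list[str]:
        return [r for r in self.values.index if self.rna_types[r] == "gene"]


@dataclass
class TargetMap:
    """miRNA -> target-RNA sets; the key set is the miRNA universe U."""

    targets: dict[str, frozenset[str]]

    def __post_init__(self):
        empty = [m for m, t in self.targets.items() if not t]
        if empty:
            raise FormatError(f"miRNA {empty[0]!r} stored with empty target set")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.targets)

    @property
    def universe_size(self) -> int:
        return len(self.targets)

    def regulators_of_rnas(self) -> dict[str, frozenset[str]]:
        """Invert the map: RNA id -> set of miRNAs targeting it."""
        inv: dict[str, set[str]] = {}
        for mirna, rnas in self.targets.items():
            for r in rnas:
                inv.setdefault(r, set()).add(mirna)
        return {r: frozenset(ms) for r, ms in inv.items()}


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "tissue", "condition", "timepoint", "hours", "replicate"]


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column {missing[0]!r}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(SampleMeta(row.sample_id, row.tissue, row.condition,
                                  row.timepoint, float(row.hours), int(row.replicate)))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    return out


def write_sample_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame([{c: getattr(s, c) for c in _META_COLS} for s in samples]) \
        .to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a TSV matrix (columns: rna_id, rna_type, one column per sample)."""
    samples = read_sample_metadata(metadata_path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "rna_id" or df.columns[1] != "rna_type":
        raise FormatError(f"{path}: first two columns must be rna_id, rna_type")
    df = df.set_index("rna_id")
    types = df.pop("rna_type")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value: {exc}") from exc
    return ExpressionMatrix(values, types, samples)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     metadata_path: str | Path) -> None:
    out = expr.values.copy()
    out.insert(0, "rna_type", expr.rna_types.reindex(out.index))
    out.index.name = "rna_id"
    out.to_csv(path, sep="\t")
    write_sample_metadata(expr.samples, metadata_path)


# ---------------------------------------------------------------------------
# miRNA target table
# ---------------------------------------------------------------------------

def read_target_table(path: str | Path) -> TargetMap:
    """Read miRNA->target pairs.

    Accepts either the minimal two-column form (miRNA id, target RNA id)
    or full psRNATarget output, from which only the miRNA and target
    accession columns are used.  Duplicate pairs collapse to one.
    """
    pairs: dict[str, set[str]] = {}
    mir_col, tgt_col = 0, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            low = [f.strip().lower() for f in fields]
            if lineno == 1 and any("mirna" in f or "acc" in f for f in low):
                # psRNATarget-style header: locate the columns by name
                for i, f in enumerate(low):
                    if "mirna" in f or f.startswith("acc"):
                        mir_col = i
                        break
                for i, f in enumerate(low):
                    if i != mir_col and ("target" in f):
                        tgt_col = i
                        break
                else:
                    tgt_col = mir_col + 1
                continue
            if len(fields) <= max(mir_col, tgt_col) or not fields[mir_col].strip() \
                    or not fields[tgt_col].strip():
                raise FormatError(f"{path}: line {lineno}: malformed target row")
            pairs.setdefault(fields[mir_col].strip(), set()).add(fields[tgt_col].strip())
    return TargetMap({m: frozenset(t) for m, t in pairs.items()})


def write_target_table(targets: TargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mirna in sorted(targets.targets):
            for rna in sorted(targets.targets[mirna]):
                fh.write(f"{mirna}\t{rna}\n")


# ---------------------------------------------------------------------------
# GO annotation table
# ---------------------------------------------------------------------------

def read_go_table(path: str | Path) -> pd.DataFrame:
    """Rows of (gene_id, go_id, go_name); go_name may be empty (cosmetic)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.split("\t")[0] == "gene_id":
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(f"{path}: line {lineno}: malformed GO row")
            rows.append((fields[0], fields[1], fields[2] if len(fields) > 2 else ""))
    return pd.DataFrame(rows, columns=["gene_id", "go_id", "go_name"])


def write_go_table(go: pd.DataFrame, path: str | Path) -> None:
    go.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# differential-expression table
# ---------------------------------------------------------------------------

def read_de_table(path: str | Path) -> pd.DataFrame:
    """Rows of (rna_id, timepoint, fdr) with FDR constrained to [0, 1]."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.split("\t")[0] == "rna_id":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: malformed DE row")
            try:
                fdr = float(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric FDR") from exc
            if not 0.0 <= fdr <= 1.0:
                raise FormatError(f"{path}: line {lineno}: FDR {fdr} outside [0, 1]")
            rows.append((fields[0], fields[1], fdr))
    df = pd.DataFrame(rows, columns=["rna_id", "timepoint", "fdr"])
    if df.duplicated(["rna_id", "timepoint"]).any():
        bad = df[df.duplicated(["rna_id", "timepoint"])].iloc[0]
        raise FormatError(f"{path}: duplicate (rna, timepoint) pair "
                          f"({bad.rna_id}, {bad.timepoint})")
    return df


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network import/export
# ---------------------------------------------------------------------------

EDGE_COLS = ["node_a", "node_b", "shared_count", "p_overlap", "rho", "p_rho"]


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    rows = []
    for a, b, d in sorted(net.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
        a, b = sorted((a, b))
        rows.append((a, b, d.get("shared_count"), d.get("p_overlap"),
                     d.get("rho"), d.get("p_rho")))
    pd.DataFrame(rows, columns=EDGE_COLS).to_csv(path, sep="\t", index=False)


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, path)


def read_graphml(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(path)
    g.graph.pop("node_default", None)
    g.graph.pop("edge_default", None)
    for n, d in g.nodes(data=True):
        if d.get("rna_type") not in RNA_TYPES:
            raise FormatError(f"{path}: node {n!r} lacks a valid rna_type attribute")
    return g


def read_edge_list(path: str | Path, rna_types: Mapping[str, str] | None = None) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing edge column {missing[0]!r}")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, shared_count=int(row.shared_count),
                   p_overlap=float(row.p_overlap), rho=float(row.rho),
                   p_rho=float(row.p_rho))
    if rna_types is not None:
        for n in g.nodes:
            g.nodes[n]["rna_type"] = rna_types[n]
    return g


# ---------------------------------------------------------------------------
# communities and annotations
# ---------------------------------------------------------------------------

def write_communities(communities, path: str | Path) -> None:
    rows = []
    for c in communities:
        for m in sorted(c.members):
            rows.append((c.community_id, m, c.score, c.seed))
    pd.DataFrame(rows, columns=["community_id", "member_id", "score", "seed_id"]) \
        .to_csv(path, sep="\t", index=False)


def read_communities(path: str | Path):
    from .mcode import Community  # local import: avoid a module cycle
    df = pd.read_csv(path, sep="\t")
    out = []
    for cid, grp in df.groupby("community_id", sort=True):
        out.append(Community(community_id=str(cid),
                             members=frozenset(grp.member_id),
                             seed=str(grp.seed_id.iloc[0]),
                             score=float(grp.score.iloc[0])))
    return out


def write_annotations(annotations, path: str | Path) -> None:
    rows = []
    for a in annotations:
        rows.append((a.lincrna_id, a.go_id, a.go_name, a.tier,
                     "" if a.p is None else a.p,
                     "" if a.community_id is None else a.community_id))
    pd.DataFrame(rows, columns=["lincrna_id", "go_id", "go_name", "tier",
                                "p", "community_id"]) \
        .to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path):
    from .annotate import LincAnnotation
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(LincAnnotation(
            lincrna_id=row.lincrna_id, go_id=row.go_id, go_name=row.go_name,
            tier=row.tier,
            p=None if row.p == "" else float(row.p),
            community_id=None if row.community_id == "" else str(row.community_id)))
    return out


# ---------------------------------------------------------------------------
# candidate-transcript attribute table
# ---------------------------------------------------------------------------

CANDIDATE_FIXED_COLS = ["transcript_id", "locus_id", "length", "class_code",
                        "sim_coverage", "sim_evalue", "cpat_coding", "cpc_coding"]


def read_candidate_table(path: str | Path):
    """Read candidate transcripts; columns after the fixed block are
    per-sample RPKM values."""
    from .filters import CandidateTranscript
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CANDIDATE_FIXED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing candidate column {missing[0]!r}")
    rpkm_cols = [c for c in df.columns if c not in CANDIDATE_FIXED_COLS]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sim = None
        if not (pd.isna(row.sim_coverage) or pd.isna(row.sim_evalue)):
            sim = (float(row.sim_coverage), float(row.sim_evalue))
        try:
            records.append(CandidateTranscript(
                transcript_id=row.transcript_id, locus_id=row.locus_id,
                length=int(row.length), class_code=str(row.class_code),
                rpkm=tuple(float(getattr(row, c)) for c in rpkm_cols),
                similarity=sim,
                coding_cpat=bool(int(row.cpat_coding)),
                coding_cpc=bool(int(row.cpc_coding))))
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    return records


def write_candidate_table(records, path: str | Path,
                          sample_names: Sequence[str] | None = None) -> None:
    n_samples = len(records[0].rpkm) if records else 0
    names = list(sample_names) if sample_names else [f"rpkm_{i+1}" for i in range(n_samples)]
    rows = []
    for r in records:
        cov, ev = (r.similarity if r.similarity is not None else (float("nan"), float("nan")))
        rows.append((r.transcript_id, r.locus_id, r.length, r.class_code, cov, ev,
                     int(r.coding_cpat), int(r.coding_cpc), *r.rpkm))
    pd.DataFrame(rows, columns=CANDIDATE_FIXED_COLS + names) \
        .to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# YAML config / truth files and bundled reference tables
# ---------------------------------------------------------------------------

def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=True)


def load_reference_key_lincrnas(tissue: str) -> pd.DataFrame:
    """Bundled key-lincRNA reports for rice root/shoot under Pi starvation
    (columns: lincrna_id, degree, go_id, go_name)."""
    if tissue not in ("root", "shoot"):
        raise ValueError(f"tissue must be 'root' or 'shoot', got {tissue!r}")
    ref = resources.files("lincnet.data").joinpath(f"key_lincrnas_{tissue}.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", keep_default_na=False)
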