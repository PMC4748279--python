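"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates the study design the pipeline targets: a
phosphate-starvation time course (nine time points, three replicates,
control vs starved) with planted ceRNA modules — blocks of genes and
lincRNAs that share a common set of miRNA regulators, co-fluctuate
through a shared latent activity, and carry a block-specific GO label.
Designated "responsive" lincRNAs are additionally up-regulated in the
starved condition from a late time point onward, so that differential
expression calls and early/late sample clustering have a known answer.

Expression model (log2 scale, exponentiated to an RPKM-like value):

    x[i, s] = mu_i + a[m(i), t(s)] + delta_i(s) + eps[i, s]

* ``mu_i ~ N(5, 1)`` — RNA baseline;
* ``a[m, t]`` — module activity: a stationary AR(1) trajectory over the
  ordered time points (lag-1 correlation ``activity_autocorr``, marginal
  sd ``module_activity_sd``), shared by replicates and by the two
  conditions.  Sharing across replicates creates the positive
  within-module rank correlation the ceRNA edge filter requires;
  sharing across conditions keeps the two arms exchangeable under a
  zero effect (the built-in DE test then has its nominal error rate);
  temporal smoothness makes neighbouring time points resemble each
  other, as real trajectories do, so sample clustering sees a
  contiguous time course;
* ``delta_i(s) = de_effect * l_i`` for every member of a *responsive*
  module in starved samples at late time points (index >=
  ``late_start_index``).  Loadings ``l_i ~ U(1 - jitter, 1 + jitter)``
  are fixed per member, so the mean up-shift is ``de_effect`` but
  amplitudes are heterogeneous, as in real stress responses;
* ``eps ~ N(0, noise_sd^2)`` — independent replicate-level noise.

Responsive modules additionally carry ``responsive_extra_genes`` extra
gene members, so their RNAs have systematically higher network degree —
responsive lincRNAs are hubs, as the key lincRNAs of the real networks
are.

Every ``simulate_*`` call derives its own random sub-stream from the
seed, so generating one table never perturbs another.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as lio
from .errors import ConfigError
from .filters import CandidateTranscript
from .io import ExpressionMatrix, SampleMeta, TargetMap

logger = logging.getLogger(__name__)

# the nine-point Pi-starvation time course: 1 h .. 21 d + 24 h
TIMEPOINT_LABELS = ("1h", "6h", "24h", "3d", "7d", "21d",
                    "21d+1h", "21d+6h", "21d+24h")
TIMEPOINT_HOURS = (1.0, 6.0, 24.0, 72.0, 168.0, 504.0, 505.0, 510.0, 528.0)

# sub-stream indices: one per generated table
_STREAM_TARGETS, _STREAM_EXPR, _STREAM_GO, _STREAM_CANDIDATES, _STREAM_FEATURES = range(5)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the generator (defaults are the
    documented recovery configuration)."""

    n_mirnas: int = 80
    n_genes: int = 120
    n_lincrnas: int = 30
    n_modules: int = 6
    module_size: int = 8           # RNAs per planted module
    lincrnas_per_module: int = 3   # remainder of each module are genes
    mirnas_per_module: int = 4
    background_target_prob: float = 0.01
    responsive_extra_genes: int = 4  # extra gene members of responsive modules
    n_timepoints: int = 9
    n_replicates: int = 3
    conditions: tuple[str, str] = ("control", "starved")
    tissue: str = "root"
    noise_sd: float = 0.2
    module_activity_sd: float = 1.0
    activity_autocorr: float = 0.5  # lag-1 correlation of module activity
    de_effect: float = 2.0          # mean log2 up-shift of responsive members
    de_effect_jitter: float = 0.5   # loadings drawn as U(1-j, 1+j)
    late_start_index: int = 4       # the 7-day position of the default course
    seed: int = 0

    def validate(self) -> None:
        counts = {"n_mirnas": self.n_mirnas, "n_genes": self.n_genes,
                  "n_lincrnas": self.n_lincrnas, "n_modules": self.n_modules,
                  "module_size": self.module_size,
                  "mirnas_per_module": self.mirnas_per_module,
                  "n_timepoints": self.n_timepoints,
                  "n_replicates": self.n_replicates}
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be a positive count, got {v}")
        n_responsive = (self.n_modules + 1) // 2
        planted_rnas = self.n_modules * self.module_size \
            + n_responsive * self.responsive_extra_genes
        if planted_rnas > self.n_genes + self.n_lincrnas:
            raise ConfigError("planted module members exceed the RNA pool")
        if self.responsive_extra_genes < 0:
            raise ConfigError("responsive_extra_genes must be >= 0")
        if self.mirnas_per_module * self.n_modules > self.n_mirnas:
            raise ConfigError("mirnas_per_module * n_modules exceeds n_mirnas")
        if not 0.0 <= self.background_target_prob <= 1.0:
            raise ConfigError("background_target_prob must be in [0, 1]")
        if min(self.noise_sd, self.module_activity_sd) < 0:
            raise ConfigError("standard deviations must be >= 0")
        if not 0.0 <= self.activity_autocorr < 1.0:
            raise ConfigError("activity_autocorr must be in [0, 1)")
        if self.de_effect < 0:
            raise ConfigError("de_effect must be >= 0")
        if not 0.0 <= self.de_effect_jitter < 1.0:
            raise ConfigError("de_effect_jitter must be in [0, 1)")
        if not 0 <= self.late_start_index < self.n_timepoints:
            raise ConfigError("late_start_index outside the time course")
        if self.lincrnas_per_module < 1 or \
                self.module_size - self.lincrnas_per_module < 2:
            raise ConfigError("each module needs >= 1 lincRNA and >= 2 genes")
        if self.n_modules * self.lincrnas_per_module > self.n_lincrnas:
            raise ConfigError("not enough lincRNAs for the planted modules")
        genes_needed = self.n_modules * (self.module_size - self.lincrnas_per_module) \
            + n_responsive * self.responsive_extra_genes
        if genes_needed > self.n_genes:
            raise ConfigError("not enough genes for the planted modules")

    # --- deterministic id layout -----------------------------------------
    def mirna_ids(self) -> list[str]:
        return [f"mir{i:04d}" for i in range(self.n_mirnas)]

    def gene_ids(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(self.n_genes)]

    def lincrna_ids(self) -> list[str]:
        return [f"linc{i:04d}" for i in range(self.n_lincrnas)]

    def timepoints(self) -> list[str]:
        if self.n_timepoints <= len(TIMEPOINT_LABELS):
            return list(TIMEPOINT_LABELS[:self.n_timepoints])
        extra = [f"t{i}" for i in range(len(TIMEPOINT_LABELS), self.n_timepoints)]
        return list(TIMEPOINT_LABELS) + extra

    def timepoint_hours(self) -> list[float]:
        hours = list(TIMEPOINT_HOURS[:self.n_timepoints])
        while len(hours) < self.n_timepoints:
            hours.append(hours[-1] + 24.0)
        return hours

    def rng(self, stream: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(5)
        return np.random.default_rng(children[stream])


@dataclass(frozen=True)
class ModuleTruth:
    module_id: str
    members: frozenset[str]
    lincrnas: frozenset[str]
    genes: frozenset[str]
    mirnas: frozenset[str]
    go_term: str
    go_name: str
    responsive: bool


@dataclass
class PlantedTruth:
    """Ground truth of one simulated data set."""

    modules: list[ModuleTruth]
    de_lincrnas: frozenset[str]
    pass_fail_labels: dict[str, str] = field(default_factory=dict)

    def module_of(self, rna_id: str) -> ModuleTruth | None:
        for m in self.modules:
            if rna_id in m.members:
                return m
        return None

    def within_module_pairs(self) -> set[tuple[str, str]]:
        pairs = set()
        for m in self.modules:
            members = sorted(m.members)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    pairs.add((a, b))
        return pairs


def _planted_modules(cfg: SimConfig) -> list[ModuleTruth]:
    genes, lincs, mirs = cfg.gene_ids(), cfg.lincrna_ids(), cfg.mirna_ids()
    gpm = cfg.module_size - cfg.lincrnas_per_module
    modules = []
    g0 = 0
    for m in range(cfg.n_modules):
        responsive = (m % 2 == 0)
        n_genes = gpm + (cfg.responsive_extra_genes if responsive else 0)
        mod_lincs = frozenset(lincs[m * cfg.lincrnas_per_module:
                                    (m + 1) * cfg.lincrnas_per_module])
        mod_genes = frozenset(genes[g0:g0 + n_genes])
        g0 += n_genes
        mod_mirs = frozenset(mirs[m * cfg.mirnas_per_module:
                                  (m + 1) * cfg.mirnas_per_module])
        modules.append(ModuleTruth(
            module_id=f"M{m:02d}",
            members=mod_lincs | mod_genes,
            lincrnas=mod_lincs, genes=mod_genes, mirnas=mod_mirs,
            go_term=f"GO:90000{m:02d}",
            go_name=f"planted process {m}",
            responsive=responsive))
    return modules


def simulate_target_map(cfg: SimConfig) -> tuple[TargetMap, PlantedTruth]:
    """Plant block-structured miRNA targeting plus independent background
    edges drawn with ``background_target_prob``."""
    cfg.validate()
    rng = cfg.rng(_STREAM_TARGETS)
    modules = _planted_modules(cfg)
    rnas = cfg.gene_ids() + cfg.lincrna_ids()
    mirs = cfg.mirna_ids()
    targets: dict[str, set[str]] = {m: set() for m in mirs}
    module_pairs = set()
    for mod in modules:
        for mir in sorted(mod.mirnas):
            for rna in sorted(mod.members):
                targets[mir].add(rna)
                module_pairs.add((mir, rna))
    if cfg.background_target_prob > 0:
        draw = rng.random((len(mirs), len(rnas))) < cfg.background_target_prob
        for i, mir in enumerate(mirs):
            for j, rna in enumerate(rnas):
                if draw[i, j] and (mir, rna) not in module_pairs:
                    targets[mir].add(rna)
    truth = PlantedTruth(
        modules=modules,
        de_lincrnas=frozenset().union(*(m.lincrnas for m in modules if m.responsive)))
    return TargetMap({m: frozenset(t) for m, t in targets.items() if t}), truth


def _check_truth(cfg: SimConfig, truth: PlantedTruth) -> None:
    expected = {m.module_id for m in _planted_modules(cfg)}
    if {m.module_id for m in truth.modules} != expected:
        raise ConfigError("planted truth does not match this configuration")


def simulate_expression(cfg: SimConfig, truth: PlantedTruth) -> ExpressionMatrix:
    """RPKM-like matrix over the full design (all conditions, time points
    and replicates) realising the planted correlation and DE structure."""
    cfg.validate()
    _check_truth(cfg, truth)
    rng = cfg.rng(_STREAM_EXPR)
    rnas = cfg.gene_ids() + cfg.lincrna_ids()
    types = pd.Series({r: ("gene" if r.startswith("gene") else "lincRNA")
                       for r in rnas})
    module_index = {r: mi for mi, mod in enumerate(truth.modules) for r in mod.members}
    tps, hours = cfg.timepoints(), cfg.timepoint_hours()

    mu = 5.0 + rng.normal(size=len(rnas))
    # stationary AR(1) module activity over the ordered time points,
    # shared by conditions and replicates
    phi = cfg.activity_autocorr
    innov = rng.normal(size=(len(truth.modules), cfg.n_timepoints))
    activity = np.empty_like(innov)
    activity[:, 0] = innov[:, 0]
    for t in range(1, cfg.n_timepoints):
        activity[:, t] = phi * activity[:, t - 1] \
            + np.sqrt(1.0 - phi ** 2) * innov[:, t]
    activity *= cfg.module_activity_sd
    # starvation response: module-level onset, per-member loading
    responsive_members = sorted(
        set().union(*(m.members for m in truth.modules if m.responsive), set()))
    loading = {r: cfg.de_effect * rng.uniform(1 - cfg.de_effect_jitter,
                                              1 + cfg.de_effect_jitter)
               for r in responsive_members}
    responsive_idx = {mi for mi, mod in enumerate(truth.modules) if mod.responsive}

    samples, columns = [], []
    starved = cfg.conditions[1]
    for ci, cond in enumerate(cfg.conditions):
        for ti, tp in enumerate(tps):
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{cfg.tissue}_{cond}_{tp}_r{rep}"
                samples.append(SampleMeta(sid, cfg.tissue, cond, tp,
                                          hours[ti], rep))
                col = mu.copy()
                for ri, rna in enumerate(rnas):
                    mi = module_index.get(rna)
                    if mi is None:
                        continue
                    col[ri] += activity[mi, ti]
                    if cond == starved and mi in responsive_idx \
                            and ti >= cfg.late_start_index:
                        col[ri] += loading[rna]
                col += rng.normal(scale=cfg.noise_sd, size=len(rnas))
                columns.append(col)
    values = pd.DataFrame(np.column_stack(columns), index=rnas,
                          columns=[s.sample_id for s in samples])
    return ExpressionMatrix(np.exp2(values), types, samples)


def simulate_go_annotations(cfg: SimConfig, truth: PlantedTruth) -> pd.DataFrame:
    """Every module gene carries its module's GO term; background genes
    carry one decoy term each; lincRNAs carry no annotation."""
    cfg.validate()
    _check_truth(cfg, truth)
    rng = cfg.rng(_STREAM_GO)
    rows = []
    for mod in truth.modules:
        for g in sorted(mod.genes):
            rows.append((g, mod.go_term, mod.go_name))
    module_genes = set().union(*(m.genes for m in truth.modules))
    decoys = [(f"GO:80000{k:02d}", f"decoy process {k}")
              for k in range(max(8, cfg.n_modules))]
    for g in cfg.gene_ids():
        if g in module_genes:
            continue
        go_id, go_name = decoys[int(rng.integers(len(decoys)))]
        rows.append((g, go_id, go_name))
    return pd.DataFrame(rows, columns=["gene_id", "go_id", "go_name"])


def simulate_candidate_transcripts(cfg: SimConfig,
                                   ) -> tuple[list[CandidateTranscript], dict[str, str]]:
    """A battery of candidate transcripts covering every rejection reason,
    the boundary cases of each rule, and clean passers, labelled with the
    expected filter outcome (``keep`` or ``reject:<reason>``)."""
    cfg.validate()
    rng = cfg.rng(_STREAM_CANDIDATES)

    def rpkms(low=False, one_high=False):
        base = rng.uniform(0.0, 0.4, size=4) if (low or one_high) \
            else rng.uniform(1.0, 20.0, size=4)
        vals = [round(float(v), 3) for v in base]
        if one_high:
            vals[2] = 0.5   # exactly at threshold in a single sample
        return tuple(vals)

    spec = [
        # (id suffix, length, class, rpkm kind, similarity, cpat, cpc, label)
        ("short", 150, "u", "hi", None, 0, 0, "reject:length"),
        ("len_boundary", 200, "u", "hi", None, 0, 0, "keep"),
        ("not_intergenic", 900, "i", "hi", None, 0, 0, "reject:intergenic"),
        ("antisense", 650, "x", "hi", None, 0, 0, "reject:intergenic"),
        ("silent", 420, "u", "low", None, 0, 0, "reject:expression"),
        ("rpkm_boundary", 510, "u", "one", None, 0, 0, "keep"),
        ("proteinlike", 800, "u", "hi", (0.6, 1e-6), 0, 0, "reject:protein_similarity"),
        ("weak_hit_eval", 800, "u", "hi", (0.6, 1e-4), 0, 0, "keep"),
        ("weak_hit_cov", 800, "u", "hi", (0.4, 1e-8), 0, 0, "keep"),
        ("cpat_coding", 1200, "u", "hi", None, 1, 0, "reject:coding_potential"),
        ("cpc_coding", 1100, "u", "hi", None, 0, 1, "reject:coding_potential"),
        ("short_and_coding", 150, "u", "hi", None, 1, 1, "reject:length"),
        ("clean1", 350, "u", "hi", None, 0, 0, "keep"),
        ("clean2", 2400, "u", "hi", (0.1, 0.5), 0, 0, "keep"),
        ("clean3", 201, "u", "hi", None, 0, 0, "keep"),
    ]
    records, labels = [], {}
    for i, (suffix, length, code, kind, sim, cpat, cpc, label) in enumerate(spec):
        tid = f"TCONS_{i:05d}_{suffix}"
        records.append(CandidateTranscript(
            transcript_id=tid, locus_id=f"XLOC_{i:06d}", length=length,
            class_code=code,
            rpkm=rpkms(low=(kind == "low"), one_high=(kind == "one")),
            similarity=sim, coding_cpat=bool(cpat), coding_cpc=bool(cpc)))
        labels[tid] = label
    return records, labels


def simulate_feature_files(cfg: SimConfig, gtf_path: str | Path,
                           fasta_path: str | Path) -> dict:
    """Write a small GTF + FASTA pair for the feature summaries: lincRNAs
    with few long exons, protein-coding transcripts with more, shorter
    exons and higher GC.  Returns the per-transcript truth."""
    cfg.validate()
    rng = cfg.rng(_STREAM_FEATURES)
    chrom, chrom_len = "chrS", 60_000
    gc_rich = "".join(rng.choice(list("GCAT"), p=[0.35, 0.35, 0.15, 0.15],
                                 size=chrom_len))
    truth: dict[str, dict] = {}
    lines = []
    pos = 100
    for i in range(6):
        biotype = "lincRNA" if i < 3 else "protein_coding"
        n_exons = int(rng.integers(1, 3)) if biotype == "lincRNA" \
            else int(rng.integers(3, 6))
        exon_len_range = (300, 800) if biotype == "lincRNA" else (80, 250)
        tid = f"SIM_T{i:03d}"
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(*exon_len_range))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(50, 200))
        attrs = (f'gene_id "SIM_G{i:03d}"; transcript_id "{tid}"; '
                 f'transcript_biotype "{biotype}";')
        lines.append(f"{chrom}\tsim\ttranscript\t{exons[0][0]}\t{exons[-1][1]}"
                     f"\t.\t+\t.\t{attrs}")
        for s, e in exons:
            lines.append(f"{chrom}\tsim\texon\t{s}\t{e}\t.\t+\t.\t{attrs}")
        exonic = "".join(gc_rich[s - 1:e] for s, e in exons)
        gc = sum(exonic.count(b) for b in "GC")
        at = sum(exonic.count(b) for b in "AT")
        truth[tid] = {"biotype": biotype,
                      "exon_lengths": [e - s + 1 for s, e in exons],
                      "gc": gc / (gc + at)}
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, chrom_len, 60):
            fh.write(gc_rich[i:i + 60] + "\n")
    return truth


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> PlantedTruth:
    """Write a complete fixture directory (all pipeline inputs plus a
    YAML truth file) and return the planted truth."""
    from .keylinc import simple_de_all_timepoints  # avoid import cycle at module load
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    targets, truth = simulate_target_map(cfg)
    expr = simulate_expression(cfg, truth)
    go = simulate_go_annotations(cfg, truth)
    candidates, labels = simulate_candidate_transcripts(cfg)
    truth.pass_fail_labels = labels
    lio.write_target_table(targets, outdir / "targets.tsv")
    lio.write_expression(expr, outdir / "expression.tsv", outdir / "samples.tsv")
    lio.write_go_table(go, outdir / "go_annotations.tsv")
    lio.write_candidate_table(candidates, outdir / "candidates.tsv")
    linc_ids = expr.lincrna_ids()
    de = simple_de_all_timepoints(
        ExpressionMatrix(expr.values.loc[linc_ids],
                         expr.rna_types[linc_ids], expr.samples),
        conditions=cfg.conditions)
    lio.write_de_table(de, outdir / "de_lincrnas.tsv")
    simulate_feature_files(cfg, outdir / "transcripts.gtf", outdir / "genome.fa")
    lio.dump_yaml({
        "config": dataclasses.asdict(cfg),
        "modules": [{
            "module_id": m.module_id,
            "members": sorted(m.members),
            "mirnas": sorted(m.mirnas),
            "go_term": m.go_term,
            "go_name": m.go_name,
            "responsive": m.responsive,
        } for m in truth.modules],
        "de_lincrnas": sorted(truth.de_lincrnas),
        "pass_fail_labels": labels,
    }, outdir / "truth.yaml")
    logger.info("simulate_dataset: wrote fixture directory %s", outdir)
    return truth
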