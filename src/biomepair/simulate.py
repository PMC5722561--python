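"""Synthetic paired tumor/non-tumor two-kingdom cohort generator.

Emulates a matched oral tumor / adjacent-normal amplicon study: a bacterial
(16S) and a fungal (ITS) genus-level count table over the same patients, with

* a shared rank-abundance baseline plus lognormal patient-level offsets,
* planted tumor-vs-normal log2 fold-changes on selected genera,
* a "field effect": in high-T-stage patients the NORMAL sample's expected
  composition is pulled toward that patient's tumor composition on the log
  scale, shrinking the pair difference,
* tissue-specific lognormal sequencing depths (tumor shallower than normal,
  occasionally below QC thresholds), and
* Dirichlet-multinomial count noise.

Every draw flows from a single :class:`numpy.random.Generator`, so a fixed
seed fixes the cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    AbundanceTable,
    PairedCohort,
    SampleRecord,
    TaxonLineage,
    ValidationError,
    build_cohort,
)

# depth distributions: (median reads, lognormal sigma); sigmas chosen so the
# lognormal quartiles approximate the asymmetry between deep non-tumor and
# shallow, highly variable tumor libraries
DEPTH_BACT_NONTUMOR = (13561, 0.587)
DEPTH_BACT_TUMOR = (6294, 2.20)
DEPTH_FUNGI_NONTUMOR = (3482, 1.05)
DEPTH_FUNGI_TUMOR = (1806, 1.16)

#: default planted tumor-vs-normal effects, (merged genus index, log2 FC):
#: a dominant genus modestly elevated plus a handful of 2-4x shifts in both
#: directions and both kingdoms (indices >= 90 are fungal)
DEFAULT_PLANTED = (
    (0, 0.63),
    (2, 1.0),
    (5, -1.5),
    (9, 1.5),
    (14, -1.8),
    (21, 2.0),
    (30, -2.0),
    (90, 1.0),
    (93, -1.5),
    (101, 2.0),
)


@dataclass
class GeneratorConfig:
    """Knobs of the cohort generator; defaults mirror the emulated study."""

    n_patients: int = 39
    n_bacterial_phyla: int = 25
    n_fungal_phyla: int = 7
    n_bacterial_genera: int = 90
    n_fungal_genera: int = 22
    planted_effects: tuple = DEFAULT_PLANTED
    frac_high_tstage: float = 0.54
    #: in [0,1]; 0 = no field effect, 1 = high-T normals share the tumor's
    #: expected composition
    field_attenuation_high: float = 0.3
    depth_lognormal_nontumor: tuple = DEPTH_BACT_NONTUMOR
    depth_lognormal_tumor: tuple = DEPTH_BACT_TUMOR
    depth_lognormal_fungi_nontumor: tuple = DEPTH_FUNGI_NONTUMOR
    depth_lognormal_fungi_tumor: tuple = DEPTH_FUNGI_TUMOR
    #: Dirichlet concentration; smaller = more overdispersed compositions
    overdispersion: float = 50.0
    #: log-scale SD of patient-level composition offsets
    patient_effect_sd: float = 0.6
    #: optional (i, j) merged-genus index pairs sharing a patient-level
    #: latent factor (induces positive abundance correlation)
    covarying_pairs: tuple = ()
    covary_sd: float = 1.0
    #: rank-abundance decay exponent of the baseline composition
    baseline_exponent: float = 1.2
    seed: int = 0

    @property
    def n_genera(self) -> int:
        return self.n_bacterial_genera + self.n_fungal_genera

    def validate(self) -> None:
        if self.n_bacterial_phyla > self.n_bacterial_genera:
            raise ValidationError("more bacterial phyla than genera")
        if self.n_fungal_phyla > self.n_fungal_genera:
            raise ValidationError("more fungal phyla than genera")
        if not 0.0 <= self.field_attenuation_high <= 1.0:
            raise ValidationError("field_attenuation_high must lie in [0, 1]")
        if self.overdispersion <= 0:
            raise ValidationError("overdispersion concentration must be > 0")
        if self.n_patients < 2:
            raise ValidationError("need at least 2 patients")
        for idx, _ in self.planted_effects:
            if not 0 <= idx < self.n_genera:
                raise ValidationError(f"planted genus index {idx} out of range")
        for i, j in self.covarying_pairs:
            if not (0 <= i < self.n_genera and 0 <= j < self.n_genera):
                raise ValidationError(f"covarying pair ({i},{j}) out of range")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery testing."""

    feature_names: list[str]
    true_log2_fc: np.ndarray  # length n_genera, merged order (bacteria, fungi)
    t_stage: dict[str, str]  # patient -> low/high
    realized_attenuation: dict[str, float]
    differential_genera: list[str]  # features with nonzero planted FC


def make_taxonomy(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[TaxonLineage], list[TaxonLineage]]:
    """Partition genera into phyla by a stick-breaking split (each phylum
    gets at least one genus)."""
    config.validate()

    def _kingdom(kingdom: str, n_phyla: int, n_genera: int, tag: str) -> list[TaxonLineage]:
        # one guaranteed genus per phylum, remainder split by Dirichlet sticks
        sizes = np.ones(n_phyla, dtype=int)
        extra = n_genera - n_phyla
        if extra > 0:
            sticks = rng.dirichlet(np.ones(n_phyla))
            sizes += rng.multinomial(extra, sticks)
        lineages = []
        g = 0
        for p in range(n_phyla):
            phylum = f"{tag}Phylum{p + 1:02d}"
            for _ in range(sizes[p]):
                g += 1
                genus = f"{tag}Genus{g:03d}"
                lineages.append(
                    TaxonLineage(
                        taxon_id=f"{kingdom}|{genus}",
                        kingdom=kingdom,
                        phylum=phylum,
                        genus=genus,
                    )
                )
        return lineages

    bact = _kingdom("bacteria", config.n_bacterial_phyla, config.n_bacterial_genera, "Bact")
    fungi = _kingdom("fungi", config.n_fungal_phyla, config.n_fungal_genera, "Fungi")
    return bact, fungi


def make_tree(lineages: Sequence[TaxonLineage], rng: np.random.Generator):
    """Random rooted tree nesting genera within phylum clades.

    Returns a :class:`skbio.TreeNode`; write with ``tree.write(path)`` to get
    newick.  Branch lengths are positive uniforms — the tree is a stand-in
    phylogeny consistent with the taxonomy, not an inferred one.
    """
    import skbio

    ids = [t.taxon_id for t in lineages]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate leaf names")
    if len(ids) < 2:
        raise ValidationError("need at least 2 leaves")
    phyla: dict[str, list[str]] = {}
    for t in lineages:
        phyla.setdefault(f"{t.kingdom}:{t.phylum}", []).append(t.taxon_id)

    def bl() -> float:
        return float(rng.uniform(0.2, 1.0))

    def join_binary(items: list[str]) -> str:
        # pairwise join (branch lengths added at join time) until one
        # subtree remains -> strictly binary topology
        while len(items) > 1:
            nxt = [
                f"({items[i]}:{bl():.6f},{items[i + 1]}:{bl():.6f})"
                for i in range(0, len(items) - 1, 2)
            ]
            if len(items) % 2:
                nxt.append(items[-1])
            items = nxt
        return items[0]

    clades = [join_binary(list(leaves)) for leaves in phyla.values()]
    root = join_binary(clades)
    if not root.startswith("("):  # single phylum with a single genus pair etc.
        root = f"({root})"
    tree = skbio.TreeNode.read([f"{root};"])
    return tree


def _draw_depth(rng: np.random.Generator, median: float, sigma: float) -> int:
    return max(1, int(round(rng.lognormal(np.log(median), sigma))))


def simulate_cohort(config: GeneratorConfig) -> tuple[PairedCohort, GroundTruth]:
    """Draw a full paired cohort and the ground truth behind it."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bact_lin, fungi_lin = make_taxonomy(config, rng)
    lineages = list(bact_lin) + list(fungi_lin)
    n_b, n_f = len(bact_lin), len(fungi_lin)
    n_g = n_b + n_f

    # baseline log composition: power-law rank-abundance within each kingdom
    base_log = np.empty(n_g)
    base_log[:n_b] = -config.baseline_exponent * np.log(np.arange(1, n_b + 1))
    base_log[n_b:] = -config.baseline_exponent * np.log(np.arange(1, n_f + 1))

    fc = np.zeros(n_g)
    for idx, log2fc in config.planted_effects:
        fc[idx] += float(log2fc)
    tumor_shift = np.log(2.0) * fc

    n_high = int(round(config.frac_high_tstage * config.n_patients))
    order = rng.permutation(config.n_patients)
    high_set = set(order[:n_high].tolist())

    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    sample_ids: list[str] = []
    metadata: list[SampleRecord] = []
    cols_b: dict[str, np.ndarray] = {}
    cols_f: dict[str, np.ndarray] = {}
    t_stage: dict[str, str] = {}
    realized: dict[str, float] = {}

    def _softmax(v: np.ndarray) -> np.ndarray:
        w = np.exp(v - v.max())
        return w / w.sum()

    def _dm_counts(comp: np.ndarray, depth: int) -> np.ndarray:
        alpha = np.maximum(config.overdispersion * comp, 1e-9)
        p = rng.dirichlet(alpha)
        if not np.all(np.isfinite(p)) or p.sum() <= 0:
            p = comp
        return rng.multinomial(depth, p / p.sum())

    for i, pid in enumerate(patients):
        stage = "high" if i in high_set else "low"
        t_stage[pid] = stage
        atten = config.field_attenuation_high if stage == "high" else 0.0
        realized[pid] = atten

        offset = rng.normal(0.0, config.patient_effect_sd, size=n_g)
        for gi, gj in config.covarying_pairs:
            z = rng.normal(0.0, config.covary_sd)
            offset[gi] += z
            offset[gj] += z
        normal_log = base_log + offset
        tumor_log = normal_log + tumor_shift
        # field effect: pull the normal sample toward the tumor profile
        normal_log = normal_log + atten * (tumor_log - normal_log)

        for tissue, logv in (("tumor", tumor_log), ("nontumor", normal_log)):
            suffix = "T" if tissue == "tumor" else "N"
            sid = f"{pid}{suffix}"
            sample_ids.append(sid)
            comp_b = _softmax(logv[:n_b])
            comp_f = _softmax(logv[n_b:])
            if tissue == "tumor":
                db = _draw_depth(rng, *config.depth_lognormal_tumor)
                df = _draw_depth(rng, *config.depth_lognormal_fungi_tumor)
            else:
                db = _draw_depth(rng, *config.depth_lognormal_nontumor)
                df = _draw_depth(rng, *config.depth_lognormal_fungi_nontumor)
            cols_b[sid] = _dm_counts(comp_b, db)
            cols_f[sid] = _dm_counts(comp_f, df)
            metadata.append(
                SampleRecord(
                    sample_id=sid,
                    patient_id=pid,
                    tissue=tissue,
                    t_stage=stage,
                    n_stage=("positive" if rng.random() < 0.49 else "negative"),
                    smoking=rng.choice(("current", "past", "never"), p=(0.18, 0.49, 0.33)),
                    age=float(np.round(np.clip(rng.normal(60.5, 13.2), 25, 90), 1)),
                    sex=("male" if rng.random() < 0.77 else "female"),
                )
            )

    bacteria = AbundanceTable(
        taxa=bact_lin,
        samples=sample_ids,
        counts=np.column_stack([cols_b[s] for s in sample_ids]),
        rank="genus",
    )
    fungi = AbundanceTable(
        taxa=fungi_lin,
        samples=sample_ids,
        counts=np.column_stack([cols_f[s] for s in sample_ids]),
        rank="genus",
    )
    cohort = build_cohort(bacteria, fungi, metadata)
    names = [t.taxon_id for t in lineages]
    truth = GroundTruth(
        feature_names=names,
        true_log2_fc=fc,
        t_stage=t_stage,
        realized_attenuation=realized,
        differential_genera=[names[i] for i in np.flatnonzero(fc)],
    )
    return cohort, truth


def degrade_to_worked_example(
    cohort: PairedCohort, n_patients: int, n_genera: int, seed: int
) -> PairedCohort:
    """Deterministic subsample to a small worked-example cohort.

    Keeps ``n_patients`` randomly chosen pairs and the ``n_genera`` most
    abundant genera (allocated between kingdoms in proportion to their table
    sizes, at least one each); pairing stays intact.
    """
    if n_patients < 2:
        raise ValidationError("need at least 2 pairs")
    if n_patients > cohort.n_pairs:
        raise ValidationError("n_patients exceeds cohort size")
    n_b_avail, n_f_avail = cohort.bacteria.n_taxa, cohort.fungi.n_taxa
    if n_genera > n_b_avail + n_f_avail or n_genera < 2:
        raise ValidationError("n_genera out of range")
    rng = np.random.default_rng(seed)
    pids = sorted(cohort.pairs)
    keep_pids = sorted(rng.choice(pids, size=n_patients, replace=False).tolist())
    keep_samples = [s for pid in keep_pids for s in cohort.pairs[pid]]

    n_keep_b = max(1, min(n_b_avail, round(n_genera * n_b_avail / (n_b_avail + n_f_avail))))
    n_keep_f = max(1, n_genera - n_keep_b)

    def _top(table: AbundanceTable, k: int) -> AbundanceTable:
        tot = table.counts.sum(axis=1)
        keep = np.sort(np.argsort(-tot, kind="stable")[:k])
        return AbundanceTable(
            taxa=[table.taxa[i] for i in keep],
            samples=list(table.samples),
            counts=table.counts[keep],
            rank=table.rank,
        )

    sub = PairedCohort(
        bacteria=_top(cohort.bacteria, n_keep_b).select_samples(keep_samples),
        fungi=_top(cohort.fungi, n_keep_f).select_samples(keep_samples),
        metadata=[r for r in cohort.metadata if r.sample_id in set(keep_samples)],
        pairs={pid: cohort.pairs[pid] for pid in keep_pids},
    )
    return sub
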