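"""Core domain types and table manipulations.

The universal input of the pipeline is a taxon-by-sample count table
(:class:`AbundanceTable`) carrying a taxonomic lineage per row, one table per
kingdom (bacteria from 16S, fungi from ITS amplicons).  Matched tumor /
non-tumor sample pairs from the same patient are organised in a
:class:`PairedCohort`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("biomepair")

KINGDOMS = ("bacteria", "fungi")
#: row granularities, finest to coarsest
RANKS = ("otu", "species", "genus", "phylum")
TISSUES = ("tumor", "nontumor")
T_STAGES = ("low", "high")
N_STAGES = ("negative", "positive")
SMOKING = ("current", "past", "never")


class ValidationError(ValueError):
    """A domain invariant was violated."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


@dataclass(frozen=True)
class TaxonLineage:
    """Taxonomic lineage of one table row.

    ``phylum`` and ``genus`` are always populated; ``species`` only at
    species/OTU granularity.
    """

    taxon_id: str
    kingdom: str
    phylum: str
    genus: str
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValidationError(f"unknown kingdom {self.kingdom!r}")
        if not self.phylum or not self.genus:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: phylum and genus must be non-empty"
            )

    def at_rank(self, rank: str) -> tuple:
        """Lineage key used for aggregation at ``rank``."""
        if rank == "phylum":
            return (self.kingdom, self.phylum)
        if rank == "genus":
            return (self.kingdom, self.phylum, self.genus)
        if rank == "species":
            return (self.kingdom, self.phylum, self.genus, self.species)
        return (self.taxon_id,)


@dataclass
class AbundanceTable:
    """Taxon-by-sample matrix with lineage annotations.

    ``counts`` holds non-negative integers for raw tables; after
    :func:`to_relative_abundance` it holds proportions (each column summing
    to 1) and ``is_relative`` is set.
    """

    taxa: list[TaxonLineage]
    samples: list[str]
    counts: np.ndarray
    rank: str = "genus"
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.taxa), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if self.rank not in RANKS:
            raise ValidationError(f"unknown rank {self.rank!r}")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample IDs")
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate taxon IDs")
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")
        if not self.is_relative and not np.allclose(self.counts, np.round(self.counts)):
            raise ValidationError("raw counts must be integral")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=self.samples)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=[t.taxon_id for t in self.taxa], columns=self.samples
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        """Column subset, preserving the requested order."""
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        idx = [pos[s] for s in sample_ids]
        return replace(self, samples=list(sample_ids), counts=self.counts[:, idx])

    def drop_empty_taxa(self) -> "AbundanceTable":
        """Remove taxa with zero total count across all samples (logged)."""
        keep = self.counts.sum(axis=1) > 0
        dropped = [t.taxon_id for t, k in zip(self.taxa, keep) if not k]
        if dropped:
            logger.info("dropping %d zero-total taxa: %s", len(dropped), dropped)
        return replace(
            self,
            taxa=[t for t, k in zip(self.taxa, keep) if k],
            counts=self.counts[keep],
        )

    def equals(self, other: "AbundanceTable") -> bool:
        return (
            self.taxa == other.taxa
            and self.samples == other.samples
            and self.rank == other.rank
            and np.array_equal(self.counts, other.counts)
        )


_UNKNOWN = (None, "", "unknown", "na", "nan")


def _norm_enum(value, allowed: tuple, field_name: str, *, required: bool = False):
    if isinstance(value, str):
        value = value.strip().lower()
    if value in _UNKNOWN:
        if required:
            raise ValidationError(f"{field_name} is required")
        return None
    if value not in allowed:
        raise ValidationError(f"invalid {field_name} value {value!r}; expected one of {allowed}")
    return value


@dataclass
class SampleRecord:
    """Clinical metadata for one tissue sample.

    Optional covariates (T-stage, N-stage, smoking, age, sex) are ``None``
    when unknown; such samples are excluded only from analyses grouped on
    that covariate.
    """

    sample_id: str
    patient_id: str
    tissue: str
    t_stage: Optional[str] = None
    n_stage: Optional[str] = None
    smoking: Optional[str] = None
    age: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        self.tissue = _norm_enum(self.tissue, TISSUES, "tissue", required=True)
        self.t_stage = _norm_enum(self.t_stage, T_STAGES, "t_stage")
        self.n_stage = _norm_enum(self.n_stage, N_STAGES, "n_stage")
        self.smoking = _norm_enum(self.smoking, SMOKING, "smoking")
        if self.age is not None:
            self.age = float(self.age)


def metadata_frame(metadata: Sequence[SampleRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in metadata])
    return df.set_index("sample_id", drop=False)


@dataclass
class PairedCohort:
    """Two kingdom tables + metadata + patient pairing map."""

    bacteria: AbundanceTable
    fungi: AbundanceTable
    metadata: list[SampleRecord]
    pairs: dict[str, tuple[str, str]]  # patient_id -> (tumor, nontumor)

    def __post_init__(self) -> None:
        known = {r.sample_id for r in self.metadata}
        for pid, (t, n) in self.pairs.items():
            for s in (t, n):
                if s not in known:
                    raise ValidationError(f"pair sample {s!r} missing from metadata")
                for table, kingdom in ((self.bacteria, "bacteria"), (self.fungi, "fungi")):
                    if s not in table.samples:
                        raise ValidationError(
                            f"pair sample {s!r} missing from {kingdom} table"
                        )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def paired_samples(self) -> list[str]:
        """All samples participating in a pair: tumors first, then normals,
        patient order preserved."""
        tumors = [t for t, _ in self.pairs.values()]
        normals = [n for _, n in self.pairs.values()]
        return tumors + normals

    def metadata_frame(self) -> pd.DataFrame:
        return metadata_frame(self.metadata)

    def table(self, kingdom: str) -> AbundanceTable:
        if kingdom == "bacteria":
            return self.bacteria
        if kingdom == "fungi":
            return self.fungi
        raise ValidationError(f"unknown kingdom {kingdom!r}")

    def restrict_to_pairs(self) -> "PairedCohort":
        """Keep only samples participating in a complete pair."""
        keep = self.paired_samples
        keep_set = set(keep)
        return PairedCohort(
            bacteria=self.bacteria.select_samples(keep),
            fungi=self.fungi.select_samples(keep),
            metadata=[r for r in self.metadata if r.sample_id in keep_set],
            pairs=dict(self.pairs),
        )


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarities."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if np.any(np.isnan(self.d)):
            raise ValidationError("NaN distances")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        if np.any(self.d < -1e-12):
            raise ValidationError("negative distances")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.d, checks=False)


# ---------------------------------------------------------------------------
# table operations


def build_cohort(
    bacteria: AbundanceTable,
    fungi: AbundanceTable,
    metadata: Sequence[SampleRecord],
) -> PairedCohort:
    """Assemble a cohort keeping only patients with a complete tumor/normal
    pair present in BOTH kingdom tables; unpaired samples are logged and
    dropped.
    """
    seen: dict[tuple[str, str], str] = {}
    for rec in metadata:
        key = (rec.patient_id, rec.tissue)
        if key in seen:
            raise ValidationError(
                f"duplicate ({rec.patient_id}, {rec.tissue}) in metadata"
            )
        seen[key] = rec.sample_id

    available = set(bacteria.samples) & set(fungi.samples)
    pairs: dict[str, tuple[str, str]] = {}
    excluded: list[str] = []
    for pid in sorted({r.patient_id for r in metadata}):
        t = seen.get((pid, "tumor"))
        n = seen.get((pid, "nontumor"))
        if t in available and n in available and t is not None and n is not None:
            pairs[pid] = (t, n)
        else:
            excluded.append(pid)
    if excluded:
        logger.warning("excluding %d patients without complete pairs: %s", len(excluded), excluded)
    if not pairs:
        raise ValidationError("zero complete tumor/non-tumor pairs")
    cohort = PairedCohort(bacteria=bacteria, fungi=fungi, metadata=list(metadata), pairs=pairs)
    return cohort.restrict_to_pairs()


def aggregate_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum rows sharing a lineage at ``rank`` (must be coarser than or equal
    to the table's own rank); per-sample totals are conserved exactly."""
    if RANKS.index(rank) < RANKS.index(table.rank):
        raise ValidationError(
            f"cannot disaggregate from {table.rank!r} to finer rank {rank!r}"
        )
    if rank == table.rank:
        return replace(table, taxa=list(table.taxa), counts=table.counts.copy())
    order: list[tuple] = []
    groups: dict[tuple, list[int]] = {}
    rep: dict[tuple, TaxonLineage] = {}
    for i, t in enumerate(table.taxa):
        key = t.at_rank(rank)
        if key not in groups:
            groups[key] = []
            order.append(key)
            rep[key] = t
        groups[key].append(i)
    new_taxa = []
    rows = np.empty((len(order), table.n_samples), dtype=float)
    for j, key in enumerate(order):
        t = rep[key]
        if rank == "phylum":
            name, genus, species = t.phylum, t.phylum, None
        elif rank == "genus":
            name, genus, species = t.genus, t.genus, None
        else:
            name, genus, species = (t.species or t.taxon_id), t.genus, t.species
        new_taxa.append(
            TaxonLineage(
                taxon_id=f"{t.kingdom}|{name}",
                kingdom=t.kingdom,
                phylum=t.phylum,
                genus=genus,
                species=species,
            )
        )
        rows[j] = table.counts[groups[key]].sum(axis=0)
    return replace(table, taxa=new_taxa, counts=rows, rank=rank)


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to within-sample proportions (columns sum to 1)."""
    totals = table.counts.sum(axis=0)
    zero = [s for s, tot in zip(table.samples, totals) if tot <= 0]
    if zero:
        raise ValidationError(f"zero-total samples cannot be normalized: {zero}")
    return replace(table, counts=table.counts / totals, is_relative=True)


def filter_low_depth_pairs(
    cohort: PairedCohort, min_reads: int = 50
) -> tuple[PairedCohort, list[str]]:
    """Drop pairs where either member's BACTERIAL total is below ``min_reads``.

    Mirrors amplicon QC practice: pairs whose tumor or normal sample yielded
    too few bacterial reads are removed entirely (both samples, both
    kingdoms) to preserve the paired design.  Returns the filtered cohort and
    the list of removed patient IDs.
    """
    totals = cohort.bacteria.sample_totals()
    removed = [
        pid
        for pid, (t, n) in cohort.pairs.items()
        if totals[t] < min_reads or totals[n] < min_reads
    ]
    if removed:
        logger.warning(
            "removing %d pairs with bacterial depth < %d: %s", len(removed), min_reads, removed
        )
    kept = {pid: p for pid, p in cohort.pairs.items() if pid not in removed}
    if not kept:
        raise ValidationError(f"all pairs removed at min_reads={min_reads}")
    filtered = PairedCohort(
        bacteria=cohort.bacteria,
        fungi=cohort.fungi,
        metadata=list(cohort.metadata),
        pairs=kept,
    ).restrict_to_pairs()
    return filtered, removed


def merge_genus_tables(
    cohort: PairedCohort, *, joint_normalization: bool = False
) -> tuple[pd.DataFrame, list[TaxonLineage]]:
    """Build the samples x genera feature matrix for classification.

    Each kingdom's table is aggregated to genus, normalized to relative
    abundance (per kingdom by default, since the two amplicon libraries have
    incomparable depths), and the columns concatenated with kingdom-prefixed
    feature names.  With ``joint_normalization`` the two count blocks are
    normalized against the combined per-sample total instead.
    """
    if set(cohort.bacteria.samples) != set(cohort.fungi.samples):
        raise ValidationError("bacteria and fungi tables cover different sample sets")
    sample_order = list(cohort.bacteria.samples)
    blocks, lineages = [], []
    tables = {
        k: aggregate_to_rank(cohort.table(k), "genus").select_samples(sample_order)
        for k in KINGDOMS
    }
    if joint_normalization:
        grand = sum(t.counts.sum(axis=0) for t in tables.values())
        zero = [s for s, tot in zip(sample_order, grand) if tot <= 0]
        if zero:
            raise ValidationError(f"zero-total samples: {zero}")
    for kingdom in KINGDOMS:
        tab = tables[kingdom]
        if joint_normalization:
            props = tab.counts / grand
        else:
            props = to_relative_abundance(tab).counts
        names = [f"{kingdom}|{t.genus}" for t in tab.taxa]
        blocks.append(pd.DataFrame(props.T, index=sample_order, columns=names))
        lineages.extend(tab.taxa)
    features = pd.concat(blocks, axis=1)
    if features.columns.duplicated().any():
        dup = features.columns[features.columns.duplicated()].tolist()
        raise ValidationError(f"duplicate feature names after merging: {dup}")
    return features, lineages
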