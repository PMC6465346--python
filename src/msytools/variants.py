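"""Multi-stage quality filter for haploid Y variant calls.

The filter restricts a VCF-like call set to single-copy Y windows and then
removes, in order: phased / multi-allelic / reference-error records; records
without a single confident call (depth >= 3 and GQ >= 9 in the same
individual); and records whose fraction of heterozygous-or-missing calls
exceeds 10%. Because the Y is haploid, heterozygous calls are treated as
unreliable evidence throughout — they count toward the bad-call fraction
and become missing when haplotypes are built.

Residual missing entries can be imputed by phylogenetic clustering
(majority state among nearest neighbours in Hamming distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .phylogeny import ANCESTRAL, DERIVED, MISSING, HaploMatrix

logger = logging.getLogger(__name__)

ALLELE_REF = "ref"
ALLELE_ALT = "alt"
ALLELE_HET = "het"
ALLELE_MISSING = "missing"

STAGE_NOT_SCY = "not_scY"
STAGE_PHASED = "phased"
STAGE_MULTIALLELIC = "multiallelic"
STAGE_REFERENCE_ERROR = "reference_error"
STAGE_LOW_QUALITY = "low_quality"
STAGE_HIGH_MISSINGNESS = "high_missingness"
STAGES = (
    STAGE_NOT_SCY,
    STAGE_PHASED,
    STAGE_MULTIALLELIC,
    STAGE_REFERENCE_ERROR,
    STAGE_LOW_QUALITY,
    STAGE_HIGH_MISSINGNESS,
)

SNV = "SNV"
INDEL = "indel"
STR = "STR"


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    allele: str  # ref | alt | het | missing
    depth: int = 0
    gq: int = 0
    phased: bool = False

    def __post_init__(self) -> None:
        if self.allele not in (ALLELE_REF, ALLELE_ALT, ALLELE_HET, ALLELE_MISSING):
            raise ValueError(f"bad allele code {self.allele!r}")
        if self.depth < 0 or self.gq < 0:
            raise ValueError("depth and gq must be >= 0")


@dataclass
class VariantRecord:
    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: list[str]
    calls: list[GenotypeCall]
    variant_id: str | None = None
    reference_error: bool = False
    str_unit: str | None = None
    str_ref_repeats: int | None = None
    raw_line: str | None = None  # original VCF body line for pass-through output
    filter_status: str = "PASS"

    @property
    def marker_type(self) -> str:
        if self.str_unit is not None:
            return STR
        if len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles):
            return SNV
        return INDEL

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos)

    def call_for(self, sample_id: str) -> GenotypeCall:
        for c in self.calls:
            if c.sample_id == sample_id:
                return c
        raise KeyError(sample_id)


@dataclass(frozen=True)
class FilterParams:
    min_depth: int = 3
    min_gq: int = 9
    max_badcall_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_gq < 0:
            raise ValueError("thresholds must be >= 0")
        if not (0 <= self.max_badcall_frac <= 1):
            raise ValueError("max_badcall_frac must lie in [0, 1]")


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in STAGES}
    )

    def check_conservation(self) -> None:
        if self.n_input != self.n_kept + sum(self.removed.values()):
            raise AssertionError("filter report does not account for every record")


def flag_reference_errors(
    variants: Sequence[VariantRecord], outgroup_id: str | None = None
) -> None:
    """Mark sites fixed for the alternate allele in every sample.

    The alt-fixed criterion (including the outgroup when named) is a stated
    completion of an unspecified rule; the flag is stored on the record so
    downstream stages and reports can identify it.
    """
    for v in variants:
        non_missing = [c for c in v.calls if c.allele != ALLELE_MISSING]
        if not non_missing:
            continue
        if outgroup_id is not None:
            try:
                og = v.call_for(outgroup_id)
            except KeyError:
                og = None
            if og is not None and og.allele != ALLELE_ALT:
                continue
        if all(c.allele == ALLELE_ALT for c in non_missing):
            v.reference_error = True


def _in_regions(
    contig: str, pos: int, regions: Mapping[str, np.ndarray]
) -> bool:
    # regions: contig -> (n, 2) array of 0-based half-open intervals, sorted
    iv = regions.get(contig)
    if iv is None or len(iv) == 0:
        return False
    p0 = pos - 1  # VCF 1-based -> 0-based
    i = int(np.searchsorted(iv[:, 0], p0, side="right")) - 1
    return i >= 0 and p0 < iv[i, 1]


def _index_regions(
    scY_regions: Sequence[tuple[str, int, int]]
) -> dict[str, np.ndarray]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in scY_regions:
        by_contig.setdefault(contig, []).append((start, end))
    out: dict[str, np.ndarray] = {}
    for contig, ivs in by_contig.items():
        arr = np.asarray(sorted(ivs), dtype=np.int64)
        if np.any(arr[1:, 0] < arr[:-1, 1]):
            raise ValueError(f"scY regions overlap on contig {contig}")
        out[contig] = arr
    return out


def filter_variants(
    variants: Sequence[VariantRecord],
    scY_regions: Sequence[tuple[str, int, int]],
    params: FilterParams = FilterParams(),
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the four filter stages in order; account for every removal.

    Stage 1 keeps only variants inside scY regions; stage 2 drops phased,
    multi-allelic and reference-error records; stage 3 requires at least one
    call with ``depth >= min_depth`` and ``gq >= min_gq`` in the same
    individual (boundaries inclusive); stage 4 drops records whose fraction
    of het-or-missing calls strictly exceeds ``max_badcall_frac``.
    """
    if not scY_regions:
        raise ValueError("scY region set is empty")
    keys = [v.key for v in variants]
    if keys != sorted(keys):
        raise ValueError("variants must be sorted by (contig, pos)")
    regions = _index_regions(scY_regions)

    report = FilterReport(n_input=len(variants))
    kept: list[VariantRecord] = []
    for v in variants:
        stage = None
        if not _in_regions(v.contig, v.pos, regions):
            stage = STAGE_NOT_SCY
        elif any(c.phased for c in v.calls):
            stage = STAGE_PHASED
        elif len(v.alt_alleles) > 1:
            stage = STAGE_MULTIALLELIC
        elif v.reference_error:
            stage = STAGE_REFERENCE_ERROR
        elif not any(
            c.depth >= params.min_depth and c.gq >= params.min_gq for c in v.calls
        ):
            stage = STAGE_LOW_QUALITY
        else:
            bad = sum(
                1 for c in v.calls if c.allele in (ALLELE_HET, ALLELE_MISSING)
            )
            if v.calls and bad / len(v.calls) > params.max_badcall_frac:
                stage = STAGE_HIGH_MISSINGNESS
        if stage is None:
            v.filter_status = "PASS"
            kept.append(v)
        else:
            v.filter_status = stage
            report.removed[stage] += 1
    report.n_kept = len(kept)
    report.check_conservation()
    return kept, report


# ---------------------------------------------------------------------------
# matrix building and imputation


def matrix_from_variants(
    variants: Sequence[VariantRecord],
    sample_ids: Sequence[str],
    outgroup_id: str | None = None,
) -> HaploMatrix:
    """Binary allelic-state matrix (ref=0, alt=1, het/missing=-1)."""
    code = {
        ALLELE_REF: ANCESTRAL,
        ALLELE_ALT: DERIVED,
        ALLELE_HET: MISSING,
        ALLELE_MISSING: MISSING,
    }
    states = np.full((len(sample_ids), len(variants)), MISSING, dtype=np.int8)
    col_ids = []
    for j, v in enumerate(variants):
        col_ids.append(v.variant_id or f"{v.contig}:{v.pos}")
        calls = {c.sample_id: c for c in v.calls}
        for i, sid in enumerate(sample_ids):
            c = calls.get(sid)
            if c is not None:
                states[i, j] = code[c.allele]
    return HaploMatrix(list(sample_ids), col_ids, states, outgroup_id)


@dataclass(frozen=True)
class ImputationEdit:
    sample_id: str
    site_id: str
    old_state: int
    new_state: int


def impute_by_clustering(
    matrix: HaploMatrix, k: int = 3
) -> tuple[HaploMatrix, list[ImputationEdit]]:
    """Fill missing entries from each sample's k nearest neighbours.

    Distance is the Hamming mismatch count over mutually non-missing sites
    (ties in neighbour rank break by sample order). Each missing entry takes
    the majority state among the neighbours' observed states; ties and
    all-missing neighbourhoods resolve to the ancestral state. Non-missing
    entries are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    S = matrix.states
    n = len(matrix.samples)
    for i in range(n):
        if np.all(S[i] == MISSING):
            raise ValueError(f"sample {matrix.samples[i]} has no observed calls")
    out = S.copy()
    edits: list[ImputationEdit] = []
    obs = S != MISSING
    for i in range(n):
        miss_cols = np.nonzero(~obs[i])[0]
        if miss_cols.size == 0:
            continue
        dists = []
        for m in range(n):
            if m == i:
                continue
            shared = obs[i] & obs[m]
            d = int(np.sum((S[i] != S[m]) & shared))
            dists.append((d, m))
        dists.sort()
        neighbours = [m for _, m in dists[:k]]
        for j in miss_cols:
            votes = [int(S[m, j]) for m in neighbours if S[m, j] != MISSING]
            derived_votes = sum(1 for v in votes if v == DERIVED)
            ancestral_votes = len(votes) - derived_votes
            new = DERIVED if derived_votes > ancestral_votes else ANCESTRAL
            out[i, j] = new
            edits.append(
                ImputationEdit(matrix.samples[i], matrix.sites[j], MISSING, new)
            )
    return (
        HaploMatrix(list(matrix.samples), list(matrix.sites), out, matrix.outgroup_id),
        edits,
    )
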