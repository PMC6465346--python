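"""Classification of assembly windows from male/female mapping coverage.

Windows are assigned to single-copy Y (scY), multi-copy Y (mcY) or non-Y
(nonMSY) classes by a Poisson likelihood-ratio model that contrasts two
hypotheses for the observed per-window mean coverages:

* MSY: males carry the window hemizygously at rate ``v * c_i / 2`` (with
  ``v`` the haploid-scaled window coverage and ``c_i`` the male's diploid
  calibration coverage), females show only mismapping background ``b_j``.
* nonMSY: everybody carries the window at diploid-scaled rate
  ``mu * c``.

All coverages enter the model in raw reads-depth units; relative coverage
``y / c`` (diploid == 1) is computed only for the scY/mcY cutoff and for
reporting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: floor for a single Poisson log-term whose rate collapsed to zero while the
#: observation is positive; near the smallest representable log-probability.
LOG_TERM_FLOOR = -745.0

MALE = "male"
FEMALE = "female"

LABEL_SCY = "scY"
LABEL_MCY = "mcY"
LABEL_NONMSY = "nonMSY"


@dataclass(frozen=True)
class SampleProfile:
    """One sequenced individual with its calibration parameters.

    ``c`` is the diploid calibration coverage (mode of PAR window mean
    coverages, raw reads-depth units); ``b`` is the female background
    coverage in the same raw units and must be absent for males.
    """

    sample_id: str
    sex: str
    c: float
    b: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (self.c > 0 and math.isfinite(self.c)):
            raise ValueError(f"{self.sample_id}: calibration coverage c must be > 0")
        if self.sex == MALE and self.b is not None:
            raise ValueError(f"{self.sample_id}: males carry no background coverage b")
        if self.b is not None:
            if self.b < 0 or not math.isfinite(self.b):
                raise ValueError(f"{self.sample_id}: b must be finite and >= 0")
            if not self.b < 0.5 * self.c:
                raise ValueError(
                    f"{self.sample_id}: background b={self.b} must be far below "
                    f"the diploid signal (b < 0.5*c = {0.5 * self.c})"
                )

    @property
    def is_male(self) -> bool:
        return self.sex == MALE

    def with_background(self, b: float) -> "SampleProfile":
        return SampleProfile(self.sample_id, self.sex, self.c, b)


@dataclass(frozen=True)
class WindowRecord:
    """A genomic window with per-sample mean coverage (raw units)."""

    contig: str
    start: int
    end: int
    y: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window {self.contig}:{self.start}-{self.end} is empty")
        for sid, val in self.y.items():
            if val < 0 or not math.isfinite(val):
                raise ValueError(f"coverage for {sid} must be finite and >= 0")

    @property
    def n_sites(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowFit:
    """Model fit for one window."""

    v_hat: float
    mu_hat: float
    log_lr: float
    posterior_msy: float
    male_rel_cov: float


@dataclass(frozen=True)
class WindowClass:
    """Final class label for one window."""

    window: WindowRecord
    label: str
    fit: WindowFit


@dataclass(frozen=True)
class ClassifierConfig:
    window_size: int = 50
    posterior_threshold: float = 0.5
    scY_cutoff: float = 1.0
    min_contig_len: int = 300
    min_y_content: float = 0.45
    min_window_sites: int = 10

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.min_contig_len <= 0:
            raise ValueError("window_size and min_contig_len must be positive")
        if not (0 < self.posterior_threshold < 1):
            raise ValueError("posterior_threshold must lie in (0, 1)")
        if self.scY_cutoff <= 0:
            raise ValueError("scY_cutoff must be positive")
        if not (0 < self.min_y_content < 1):
            raise ValueError("min_y_content must lie in (0, 1)")


# ---------------------------------------------------------------------------
# calibration


def estimate_diploid_calibration(par_window_coverages: Sequence[float]) -> float:
    """Diploid calibration coverage ``c`` from PAR window mean coverages.

    The mode of the empirical distribution is taken as the histogram argmax
    with unit-width bins anchored at integers; ties break toward the smaller
    bin, and the returned value is the mean of the coverages in the winning
    bin (identical to the bin value for integer-valued depth data).
    """
    values = np.asarray(par_window_coverages, dtype=float)
    if values.size == 0:
        raise ValueError("cannot calibrate from an empty set of PAR windows")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("PAR window coverages must be finite and >= 0")
    bins = np.floor(values).astype(np.int64)
    counts = np.bincount(bins)
    mode_bin = int(np.argmax(counts))  # argmax returns the first == smaller bin
    c = float(values[bins == mode_bin].mean())
    if c <= 0:
        raise ValueError("modal PAR coverage is zero; sample unusable for calibration")
    return c


def estimate_female_background(window_coverages: Sequence[float]) -> float:
    """Female background ``b``: mean raw coverage over trusted scY windows."""
    values = np.asarray(window_coverages, dtype=float)
    if values.size == 0:
        raise ValueError(
            "no seed scY windows supplied; provide trusted regions or enable "
            "the two-pass mode"
        )
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("coverages must be finite and >= 0")
    return float(values.mean())


# ---------------------------------------------------------------------------
# per-window model


def _split_sexes(
    window: WindowRecord, profiles: Sequence[SampleProfile]
) -> tuple[list[tuple[float, SampleProfile]], list[tuple[float, SampleProfile]]]:
    males, females = [], []
    for p in profiles:
        try:
            y = window.y[p.sample_id]
        except KeyError:
            raise KeyError(
                f"window {window.contig}:{window.start}-{window.end} has no "
                f"coverage entry for sample {p.sample_id!r}"
            ) from None
        (males if p.is_male else females).append((y, p))
    if not males or not females:
        raise ValueError("the model needs at least one male and one female")
    return males, females


def fit_window_models(
    window: WindowRecord, profiles: Sequence[SampleProfile]
) -> tuple[float, float]:
    """Closed-form MLEs (v_hat, mu_hat) for the MSY and nonMSY models."""
    males, females = _split_sexes(window, profiles)
    male_y = sum(y for y, _ in males)
    male_half_c = sum(p.c / 2.0 for _, p in males)
    all_y = male_y + sum(y for y, _ in females)
    all_c = sum(p.c for _, p in males) + sum(p.c for _, p in females)
    v_hat = male_y / male_half_c
    mu_hat = all_y / all_c
    return v_hat, mu_hat


def _pois_logterm(y: float, lam: float) -> float:
    # log Poisson mass with the factorial dropped; 0*ln(0) := 0
    if lam > 0:
        return y * math.log(lam) - lam
    return 0.0 if y == 0 else LOG_TERM_FLOOR


def window_log_lr(
    window: WindowRecord, profiles: Sequence[SampleProfile]
) -> WindowFit:
    """Log likelihood-ratio (MSY over nonMSY) and posterior for one window.

    Factorial terms are omitted throughout because they cancel in the
    ratio, which also makes fractional mean coverages well defined.
    """
    males, females = _split_sexes(window, profiles)
    v_hat, mu_hat = fit_window_models(window, profiles)

    msy = 0.0
    non = 0.0
    for y, p in males:
        msy += _pois_logterm(y, v_hat * p.c / 2.0)
        non += _pois_logterm(y, mu_hat * p.c)
    for y, p in females:
        if p.b is None:
            raise ValueError(f"female {p.sample_id} has no background coverage b")
        msy += _pois_logterm(y, p.b)
        non += _pois_logterm(y, mu_hat * p.c)

    log_lr = msy - non
    # logistic(log_lr) under equal priors, overflow-safe
    if log_lr >= 0:
        posterior = 1.0 / (1.0 + math.exp(-log_lr))
    else:
        posterior = math.exp(log_lr) / (1.0 + math.exp(log_lr))
    male_rel_cov = float(np.mean([y / p.c for y, p in males]))
    return WindowFit(v_hat, mu_hat, log_lr, posterior, male_rel_cov)


def classify_windows(
    windows: Iterable[WindowRecord],
    profiles: Sequence[SampleProfile],
    config: ClassifierConfig = ClassifierConfig(),
) -> list[WindowClass]:
    """Label every usable window scY / mcY / nonMSY.

    Windows shorter than ``config.min_window_sites`` are dropped (a Poisson
    mean over very few sites is unstable); the drop is logged.
    """
    out: list[WindowClass] = []
    n_dropped = 0
    for window in windows:
        if window.n_sites < config.min_window_sites:
            n_dropped += 1
            continue
        fit = window_log_lr(window, profiles)
        if fit.posterior_msy < config.posterior_threshold:
            label = LABEL_NONMSY
        elif fit.male_rel_cov <= config.scY_cutoff:
            label = LABEL_SCY
        else:
            label = LABEL_MCY
        out.append(WindowClass(window, label, fit))
    if n_dropped:
        logger.warning(
            "dropped %d windows shorter than %d sites from classification",
            n_dropped,
            config.min_window_sites,
        )
    return out


# ---------------------------------------------------------------------------
# contig filtering


@dataclass
class ContigSummary:
    contig: str
    length: int
    n_windows: int
    scY_bp: int = 0
    mcY_bp: int = 0
    nonMSY_bp: int = 0
    y_content: float = 0.0
    kept: bool = False


def filter_contigs(
    classes: Sequence[WindowClass],
    contig_lengths: Mapping[str, int],
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[set[str], dict[str, ContigSummary]]:
    """Keep contigs by Y content and length; report per-class bp totals.

    A contig is kept iff the fraction of its windows labelled scY or mcY is
    at least ``min_y_content`` and its length is at least ``min_contig_len``.
    """
    summaries: dict[str, ContigSummary] = {
        contig: ContigSummary(contig, int(length), 0)
        for contig, length in contig_lengths.items()
    }
    msy_windows: dict[str, int] = {c: 0 for c in contig_lengths}
    for wc in classes:
        contig = wc.window.contig
        if contig not in summaries:
            raise KeyError(f"window on unknown contig {contig!r}")
        s = summaries[contig]
        s.n_windows += 1
        bp = wc.window.n_sites
        if wc.label == LABEL_SCY:
            s.scY_bp += bp
            msy_windows[contig] += 1
        elif wc.label == LABEL_MCY:
            s.mcY_bp += bp
            msy_windows[contig] += 1
        else:
            s.nonMSY_bp += bp

    kept: set[str] = set()
    for contig, s in summaries.items():
        if s.n_windows == 0:
            logger.warning("contig %s has no classified windows; discarded", contig)
            continue
        s.y_content = msy_windows[contig] / s.n_windows
        if s.y_content >= config.min_y_content and s.length >= config.min_contig_len:
            s.kept = True
            kept.add(contig)
    return kept, summaries


# ---------------------------------------------------------------------------
# two-pass background estimation


def estimate_backgrounds_two_pass(
    windows: Sequence[WindowRecord],
    profiles: Sequence[SampleProfile],
    config: ClassifierConfig = ClassifierConfig(),
) -> list[SampleProfile]:
    """Estimate female backgrounds without a trusted seed BED.

    First pass classifies with every female's ``b`` initialised to
    ``0.1 * c``; each female's background is then re-estimated as her mean
    raw coverage over first-pass scY windows. The caller reclassifies once
    with the returned profiles.
    """
    provisional = [
        p if p.is_male or p.b is not None else p.with_background(0.1 * p.c)
        for p in profiles
    ]
    first_pass = classify_windows(windows, provisional, config)
    scy_windows = [wc.window for wc in first_pass if wc.label == LABEL_SCY]
    if not scy_windows:
        raise ValueError("first pass produced no scY windows; cannot estimate b")
    out: list[SampleProfile] = []
    for p in profiles:
        if p.is_male:
            out.append(p)
        else:
            b = estimate_female_background(
                [w.y[p.sample_id] for w in scy_windows]
            )
            out.append(p.with_background(b))
    return out
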