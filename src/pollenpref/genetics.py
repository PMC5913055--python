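"""Gametophytic transmission genetics: transmission efficiency, segregation chi-square, proportions.

For a heterozygote x wild-type cross of a gametophyte-acting allele, each
progeny plant records one transmission event through the segregating gamete
class: wild-type progeny carry the wild-type allele, heterozygous progeny
the mutant allele (homozygotes are structurally impossible). Transmission
efficiency (TE) is the percentage of mutant-allele transmissions relative
to wild-type-allele transmissions, 100 * het / WT. Mendelian transmission
gives a 1:1:0 WT:het:hom progeny ratio, tested by Pearson chi-square over
the classes with positive expected weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .enrichment import round_half_up
from .io import CrossCounts, ValidationError


class UndefinedTEError(ValidationError):
    """No wild-type transmissions observed: TE is undefined (division by
    zero), which signals total wild-type-allele transmission failure and is
    distinct from TE = 0 (no mutant transmissions)."""


@dataclass
class TransmissionResult:
    cross_label: str
    te: float       # percent, 1 dp
    chi2: float
    df: int
    p_value: float
    distorted: bool  # segregation-distortion flag


def transmission_efficiency(counts: CrossCounts) -> float:
    """TE = 100 * n_heterozygote / n_wild_type, rounded half-up to 1 dp."""
    if counts.n_wild_type == 0:
        raise UndefinedTEError(
            f"cross {counts.cross_label!r}: no wild-type progeny; TE undefined")
    return round_half_up(100.0 * counts.n_heterozygote / counts.n_wild_type, 1)


def chi_square_segregation(counts: CrossCounts,
                           expected_ratio: tuple[float, float, float] = (1, 1, 0),
                           yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square of observed genotype counts against a ratio.

    Classes with expected weight 0 must have observed count 0 (the 1:1:0
    null makes the homozygote class structurally empty) and are excluded
    from the statistic; df = number of positive-weight classes - 1. No
    continuity correction unless ``yates=True``.
    """
    observed = np.array([counts.n_wild_type, counts.n_heterozygote,
                         counts.n_homozygote], dtype=float)
    weights = np.asarray(expected_ratio, dtype=float)
    if (weights < 0).any():
        raise ValidationError("expected ratio weights must be >= 0")
    zero_classes = weights == 0
    if (observed[zero_classes] > 0).any():
        raise ValidationError(
            f"cross {counts.cross_label!r}: observed counts in classes with "
            "expected weight 0; the stated ratio is impossible")
    obs = observed[~zero_classes]
    w = weights[~zero_classes]
    if len(obs) < 2:
        raise ValidationError("need >= 2 classes with positive expected weight")
    total = obs.sum()
    if total == 0:
        raise ValidationError("zero total progeny count")
    expected = total * w / w.sum()
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float(np.sum(diff ** 2 / expected))
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def analyze_cross(counts: CrossCounts,
                  expected_ratio: tuple[float, float, float] = (1, 1, 0),
                  alpha: float = 0.05) -> TransmissionResult:
    """TE + chi-square + segregation-distortion flag for one cross.

    A cross is flagged distorted when the segregation test rejects at
    ``alpha`` AND the mutant allele is under-transmitted (TE < 50%).
    """
    te = transmission_efficiency(counts)
    chi2, df, p = chi_square_segregation(counts, expected_ratio)
    return TransmissionResult(counts.cross_label, te, chi2, df, p,
                              distorted=(p < alpha and te < 50.0))


def proportion(successes: int, trials: int,
               confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Percentage (2 dp, round-half-up) with an exact Clopper-Pearson CI.

    Returns (percent, (lower_percent, upper_percent)).
    """
    if trials <= 0:
        raise ValidationError("trials must be > 0")
    if not (0 <= successes <= trials):
        raise ValidationError("successes must be in [0, trials]")
    percent = round_half_up(100.0 * successes / trials, 2)
    alpha = 1.0 - confidence
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return percent, (100.0 * lo, 100.0 * hi)
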