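"""Bisulfite-sequencing methylation quantification and differential testing.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T)
while 5-methylcytosine resists conversion and reads as C.  The per-site
methylation level is therefore the fraction of unconverted reads.  Incomplete
conversion inflates apparent methylation; given a conversion efficiency ``e``
estimated from known-unmethylated control sites, the observed level

    observed = m + (1 - m) * (1 - e)

is inverted to recover the true level ``m``.

Site coordinates are 1-based throughout, matching the rRNA convention in
which the NSUN5 target is written C3782 on the human 28S rRNA.

Differential site methylation uses an empirical-Bayes moderated t-test:
per-site sample variances (of variance-stabilized replicate levels) are
shrunk toward a prior fitted by moment matching on log variances, gaining
degrees of freedom at small replicate numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

__all__ = [
    "ModeratedTPrior",
    "CloneMatrix",
    "methylation_level",
    "estimate_conversion_efficiency",
    "correct_for_conversion",
    "pooled_site_levels",
    "call_high_methylation_sites",
    "site_level_matrix",
    "fit_moderated_prior",
    "moderated_t_site_test",
    "convert_reference",
    "queried_cytosines",
    "clone_analysis",
    "render_lollipop",
]

_VALID_BASES = set("ACGTUN")


# ---------------------------------------------------------------------------
# levels and conversion correction


def methylation_level(unconverted, coverage):
    """Per-site methylation level = unconverted / coverage.

    Zero coverage yields NaN (missing, not 0).  ``unconverted > coverage``
    is a data error.
    """
    unconverted = np.asarray(unconverted, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    if np.any(unconverted > coverage):
        raise ValueError("unconverted count exceeds coverage")
    if np.any(unconverted < 0) or np.any(coverage < 0):
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        level = np.where(coverage > 0, unconverted / np.where(coverage > 0, coverage, 1.0),
                         np.nan)
    if level.ndim == 0:
        return float(level)
    return level


def estimate_conversion_efficiency(pileup: pd.DataFrame, control_sites) -> float:
    """Conversion efficiency from declared known-unmethylated control sites:
    1 - (pooled unconverted / pooled coverage)."""
    sub = pileup[pileup["site"].isin(list(control_sites))]
    cov = sub["coverage"].sum()
    if len(sub) == 0 or cov == 0:
        raise ValueError("no covered control sites")
    return 1.0 - sub["unconverted"].sum() / cov


def correct_for_conversion(observed_level, efficiency: float):
    """Invert observed = m + (1-m)(1-e): m = (observed - (1-e)) / e,
    clipped to [0, 1] (clipping emits a warning)."""
    if not 0 < efficiency <= 1:
        raise ValueError("conversion efficiency must lie in (0, 1]")
    observed = np.asarray(observed_level, dtype=float)
    corrected = (observed - (1.0 - efficiency)) / efficiency
    clipped = np.clip(corrected, 0.0, 1.0)
    n_clip = np.sum((corrected < 0) | (corrected > 1))
    if n_clip:
        warnings.warn(f"clipped {int(n_clip)} corrected level(s) into [0, 1]")
    if clipped.ndim == 0:
        return float(clipped)
    return clipped


# ---------------------------------------------------------------------------
# site calling


def pooled_site_levels(pileup: pd.DataFrame, condition,
                       conversion_efficiency: float | None = None) -> pd.DataFrame:
    """Per-site levels pooled across the replicate libraries of one
    condition; optionally conversion-corrected.  Returns a DataFrame with
    columns site, coverage, unconverted, level."""
    if condition not in set(pileup["condition"]):
        raise ValueError(f"condition {condition!r} absent from pileup")
    sub = pileup[pileup["condition"] == condition]
    agg = sub.groupby("site", as_index=False)[["coverage", "unconverted"]].sum()
    agg["level"] = methylation_level(agg["unconverted"].to_numpy(),
                                     agg["coverage"].to_numpy())
    if conversion_efficiency is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            agg["level"] = correct_for_conversion(agg["level"].to_numpy(),
                                                  conversion_efficiency)
    return agg


def call_high_methylation_sites(pileup: pd.DataFrame, condition,
                                threshold: float = 0.90,
                                min_coverage: int = 30,
                                conversion_efficiency: float | None = None) -> pd.DataFrame:
    """Sites whose pooled methylation level in ``condition`` strictly exceeds
    ``threshold`` (default 0.90: "over 90%") at pooled coverage >=
    ``min_coverage``, sorted by level descending."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    agg = pooled_site_levels(pileup, condition, conversion_efficiency)
    hits = agg[(agg["coverage"] >= min_coverage) & (agg["level"] > threshold)]
    return hits.sort_values("level", ascending=False).reset_index(drop=True)


def site_level_matrix(pileup: pd.DataFrame, condition,
                      conversion_efficiency: float | None = None) -> pd.DataFrame:
    """Per-library methylation levels for one condition, sites x libraries."""
    if condition not in set(pileup["condition"]):
        raise ValueError(f"condition {condition!r} absent from pileup")
    sub = pileup[pileup["condition"] == condition].copy()
    sub["level"] = methylation_level(sub["unconverted"].to_numpy(),
                                     sub["coverage"].to_numpy())
    if conversion_efficiency is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub["level"] = correct_for_conversion(sub["level"].to_numpy(),
                                                  conversion_efficiency)
    return sub.pivot(index="site", columns="library", values="level")


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


@dataclass(frozen=True)
class ModeratedTPrior:
    """Scaled inverse-chi-square variance prior: s0_squared is the prior
    variance, d0 the prior degrees of freedom (np.inf allowed)."""

    s0_squared: float
    d0: float

    def __post_init__(self):
        if self.s0_squared <= 0:
            raise ValueError("s0_squared must be positive")
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone decreasing
    trigamma; standard initialisation x ~ 0.5 + 1/y)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def fit_moderated_prior(site_variances, residual_df: float) -> ModeratedTPrior:
    """Fit the variance prior by matching the first two moments of log sample
    variances to the scaled-F model s^2 ~ s0^2 F(d, d0).

    Under that model Var[log s^2] = trigamma(d/2) + trigamma(d0/2); the
    excess of the observed log-variance spread over trigamma(d/2) determines
    d0 by trigamma inversion, and the mean determines s0^2.  Near-constant
    variances give d0 = inf (complete shrinkage).  All-zero variances fall
    back to d0 = inf with a floor prior variance, with a warning.
    """
    v = np.asarray(site_variances, dtype=float)
    v = v[np.isfinite(v)]
    if np.all(v <= 0):
        warnings.warn("all sample variances are zero; using a floor prior variance")
        return ModeratedTPrior(s0_squared=1e-12, d0=np.inf)
    v = v[v > 0]
    if v.size < 2:
        raise ValueError("need >= 2 finite positive sample variances")
    if v.size < 10:
        warnings.warn("fewer than 10 positive variances; prior estimate is low-confidence")
    d = float(residual_df)
    z = np.log(v)
    e_mean = z.mean()
    e_var = z.var(ddof=1)
    if e_var == 0.0:
        # observed variances are literally constant; the scaled-F model is
        # degenerate and the natural prior is that common value
        return ModeratedTPrior(s0_squared=float(np.exp(e_mean)), d0=np.inf)
    excess = e_var - polygamma(1, d / 2.0)
    if excess <= 0:
        d0 = np.inf
        log_s0 = e_mean - (digamma(d / 2.0) - np.log(d / 2.0))
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        log_s0 = (e_mean - (digamma(d / 2.0) - np.log(d / 2.0))
                  + (digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModeratedTPrior(s0_squared=float(np.exp(log_s0)), d0=float(d0))


def _stabilize(levels: np.ndarray, transform: str) -> np.ndarray:
    if transform == "arcsine":
        return np.arcsin(np.sqrt(np.clip(levels, 0.0, 1.0)))
    if transform == "none":
        return levels
    raise ValueError(f"unknown transform {transform!r}")


def moderated_t_site_test(levels_a, levels_b, prior: ModeratedTPrior | None = None,
                          transform: str = "arcsine",
                          sites=None) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test per site on replicate-level
    methylation proportions.

    ``levels_a``/``levels_b`` are (sites x replicates) arrays.  Levels are
    variance-stabilized (arcsine-square-root by default; ``transform="none"``
    for raw proportions), the pooled sample variance is shrunk to the
    posterior value s~^2 = (d0*s0^2 + d*s^2)/(d0 + d), and

        t = (mean_B - mean_A) / (s~ * sqrt(1/nA + 1/nB))

    is referred to t with d0 + d degrees of freedom (normal when d0 = inf).
    With d0 = 0 this is exactly the ordinary pooled-variance two-sample t.
    When ``prior`` is None it is fitted from the data.  Sites with a missing
    replicate are reported with NaN statistics and excluded from the FDR.
    """
    a = np.atleast_2d(np.asarray(levels_a, dtype=float))
    b = np.atleast_2d(np.asarray(levels_b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("levels_a and levels_b must cover the same sites")
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a + n_b < 2 or min(n_a, n_b) < 1:
        raise ValueError("need >= 2 replicates in total and >= 1 per condition")
    d = n_a + n_b - 2
    if d < 1:
        raise ValueError("no residual degrees of freedom for the pooled variance")

    ta = _stabilize(a, transform)
    tb = _stabilize(b, transform)
    complete = np.isfinite(ta).all(axis=1) & np.isfinite(tb).all(axis=1)
    n_missing = int((~complete).sum())
    if n_missing:
        warnings.warn(f"{n_missing} site(s) with missing replicates reported as NaN")

    mean_a = ta.mean(axis=1)
    mean_b = tb.mean(axis=1)
    var_a = ta.var(axis=1, ddof=1) if n_a > 1 else np.zeros(a.shape[0])
    var_b = tb.var(axis=1, ddof=1) if n_b > 1 else np.zeros(a.shape[0])
    s2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / d

    if prior is None:
        prior = fit_moderated_prior(s2[complete], residual_df=d)

    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_squared)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_squared + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d

    denom = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_b - mean_a) / denom
    t = np.where(denom == 0, 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    t[~complete] = np.nan
    p[~complete] = np.nan

    fdr = np.full_like(p, np.nan)
    if complete.any():
        fdr[complete] = _bh(p[complete])

    if sites is None:
        sites = np.arange(1, a.shape[0] + 1)
    return pd.DataFrame({
        "site": np.asarray(sites),
        "mean_level_A": np.nanmean(a, axis=1),
        "mean_level_B": np.nanmean(b, axis=1),
        "delta": np.nanmean(b, axis=1) - np.nanmean(a, axis=1),
        "moderated_t": t,
        "df_total": np.full(a.shape[0], df_total, dtype=float),
        "p_value": p,
        "fdr": fdr,
    })


def _bh(p):
    # local import to avoid a cycle at module import time
    from .te import bh_fdr
    return bh_fdr(p)


# ---------------------------------------------------------------------------
# reference conversion and clone analysis


def convert_reference(sequence: str, mode: str = "all_c") -> str:
    """In-silico bisulfite conversion of a reference sequence.

    ``all_c``: every C reads T (RNA mode; U on input is treated as T).
    ``cpg_only``: C converts to T except when followed by G (DNA CpG-island
    amplicons, where CpG cytosines are the queried, potentially methylated
    positions)."""
    seq = sequence.upper().replace("U", "T")
    bad = [i + 1 for i, ch in enumerate(seq) if ch not in _VALID_BASES]
    if bad:
        raise ValueError(f"invalid characters at 1-based positions {bad}")
    if mode == "all_c":
        return seq.replace("C", "T")
    if mode == "cpg_only":
        out = list(seq)
        for i, ch in enumerate(out):
            if ch == "C" and not (i + 1 < len(out) and out[i + 1] == "G"):
                out[i] = "T"
        return "".join(out)
    raise ValueError(f"unknown mode {mode!r}")


def queried_cytosines(sequence: str, mode: str = "all_c") -> list:
    """1-based positions of the queried cytosines of a reference under the
    chosen mode (all cytosines, or CpG-context cytosines only)."""
    seq = sequence.upper().replace("U", "T")
    bad = [i + 1 for i, ch in enumerate(seq) if ch not in _VALID_BASES]
    if bad:
        raise ValueError(f"invalid characters at 1-based positions {bad}")
    if mode == "all_c":
        return [i + 1 for i, ch in enumerate(seq) if ch == "C"]
    if mode == "cpg_only":
        return [i + 1 for i, ch in enumerate(seq)
                if ch == "C" and i + 1 < len(seq) and seq[i + 1] == "G"]
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class CloneMatrix:
    """Per-clone x per-cytosine methylation calls from bisulfite amplicon
    clone sequencing, with per-position frequencies (ambiguous calls excluded
    from denominators) and per-clone percent methylation."""

    clone_ids: list
    positions: list
    calls: pd.DataFrame  # clones x positions, values in {methylated, unmethylated, ambiguous}
    per_position_frequency: pd.Series
    per_clone_percent: pd.Series


def clone_analysis(clones, reference: str, mode: str = "all_c",
                   min_clones: int = 8) -> CloneMatrix:
    """Score bisulfite clone sequences against a reference amplicon.

    ``clones`` is a list of Bio.SeqRecord (or (id, sequence) pairs) of the
    same length as ``reference``.  At each queried cytosine, C is called
    methylated, T unmethylated, anything else ambiguous.  A warning is issued
    when fewer than ``min_clones`` clones are supplied (the benchmark design
    interrogates at least eight single clones per sample).
    """
    ref = reference.upper().replace("U", "T")
    positions = queried_cytosines(ref, mode)
    if not positions:
        raise ValueError("reference contains no queried cytosine under this mode")
    records = []
    for rec in clones:
        if hasattr(rec, "seq"):
            records.append((rec.id, str(rec.seq).upper().replace("U", "T")))
        else:
            name, seq = rec
            records.append((name, str(seq).upper().replace("U", "T")))
    if len(records) < min_clones:
        warnings.warn(f"only {len(records)} clones supplied (< {min_clones})")
    for name, seq in records:
        if len(seq) != len(ref):
            raise ValueError(f"clone {name!r} length {len(seq)} != reference length {len(ref)}")

    call_of = {"C": "methylated", "T": "unmethylated"}
    rows = {}
    for name, seq in records:
        rows[name] = [call_of.get(seq[p - 1], "ambiguous") for p in positions]
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=positions)

    meth = (calls == "methylated").sum(axis=0)
    unmeth = (calls == "unmethylated").sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = meth / (meth + unmeth)
    clone_meth = (calls == "methylated").sum(axis=1)
    clone_unmeth = (calls == "unmethylated").sum(axis=1)
    clone_pct = 100.0 * clone_meth / (clone_meth + clone_unmeth)

    return CloneMatrix(
        clone_ids=[name for name, _ in records],
        positions=positions,
        calls=calls,
        per_position_frequency=freq,
        per_clone_percent=clone_pct,
    )


def render_lollipop(matrix: CloneMatrix) -> str:
    """Text rendering of a clone matrix, one clone per row: filled circles
    for methylated cytosines, open circles for unmethylated, a dot for
    ambiguous calls; per-clone percent appended, per-position frequencies in
    a footer."""
    sym = {"methylated": "●", "unmethylated": "○", "ambiguous": "·"}
    width = max(len(str(c)) for c in matrix.clone_ids)
    lines = []
    for clone in matrix.clone_ids:
        row = "".join(sym[v] for v in matrix.calls.loc[clone])
        pct = matrix.per_clone_percent.loc[clone]
        lines.append(f"{clone:<{width}}  {row}  {pct:5.1f}%")
    freqs = " ".join(f"{p}:{f:.2f}" for p, f in matrix.per_position_frequency.items())
    lines.append(f"{'freq':<{width}}  {freqs}")
    return "\n".join(lines)
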