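"""Attentional modulation indices, dominance analysis, and FDR statistics.

The attentional modulation index of a nonnegative measure F (spectral
power, coherence, or cGC) is MI = (F_RF - F_OUT) / (F_RF + F_OUT), where
RF is the attend-toward condition and OUT pools the two attend-away
conditions by random subsampling of an equal trial count from each.
Significance across sessions uses two-sided Wilcoxon signed-rank tests
with Benjamini-Hochberg FDR control at q = 0.05 within frequency-band
families.  Dominance matrices encode, per band, which direction of each
contact pair carries significantly stronger cGC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .laminar import COMPARTMENTS
from .spectral import TimeFreqMap


@dataclass
class MIResult:
    measure: str
    mi: np.ndarray
    p: Optional[np.ndarray] = None
    q: Optional[np.ndarray] = None
    significant: Optional[np.ndarray] = None
    n_undefined: int = 0
    skipped: Optional[np.ndarray] = None


@dataclass
class DominanceMatrix:
    """Signed per-band dominance of directed cGC between contact pairs.

    Entry (i, j) is +strength when i->j significantly exceeds j->i,
    -strength for the reverse, and 0 when the directional difference is
    not significant; (i, j) and (j, i) are never both nonzero with the
    same sign.
    """

    band: str
    matrix: np.ndarray
    q: float = 0.05
    normalization: str = "raw"


def pool_attend_out(
    trials_out1: np.ndarray,
    trials_out2: np.ndarray,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Pooled attend-away trial set: equal random subsamples of OUT1/OUT2.

    Draws k = min(n_out1, n_out2) trials from each condition without
    replacement (seeded) and concatenates, so both away conditions
    contribute equally.
    """
    t1 = np.asarray(trials_out1)
    t2 = np.asarray(trials_out2)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both OUT conditions must be non-empty")
    k = min(t1.size, t2.size)
    rng = np.random.default_rng(seed)
    return np.concatenate([
        rng.choice(t1, size=k, replace=False),
        rng.choice(t2, size=k, replace=False),
    ])


def modulation_index(f_rf: np.ndarray, f_out: np.ndarray) -> np.ndarray:
    """Elementwise MI = (F_RF - F_OUT) / (F_RF + F_OUT).

    Exactly antisymmetric under swapping the two inputs; lies in [-1, 1]
    for nonnegative measures.  Cells where both inputs are zero are
    undefined and returned as NaN.
    """
    a = np.asarray(f_rf, dtype=float)
    b = np.asarray(f_out, dtype=float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = (a - b) / denom
    return np.where(denom == 0, np.nan, mi)


def bh_mask(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level q."""
    rej, _, _, _ = multipletests(np.asarray(pvals, dtype=float), alpha=q,
                                 method="fdr_bh")
    return rej


def wilcoxon_fdr(
    families: dict,
    q: float = 0.05,
    min_pairs: int = 5,
) -> dict:
    """Two-sided Wilcoxon signed-rank tests with BH FDR within families.

    ``families`` maps a family name (typically a frequency band) to an
    array (n_tests, n_subjects) of paired differences (or to a tuple
    (a, b) of equal-shape arrays).  Tests with fewer than ``min_pairs``
    non-tied pairs are skipped (p = NaN, flagged).  Returns per family a
    dict with p, q values and the rejection mask at level ``q``.
    """
    out = {}
    for name, data in families.items():
        if isinstance(data, tuple):
            diffs = np.asarray(data[0], dtype=float) - np.asarray(data[1], dtype=float)
        else:
            diffs = np.asarray(data, dtype=float)
        diffs = np.atleast_2d(diffs)
        n_tests = diffs.shape[0]
        p = np.full(n_tests, np.nan)
        skipped = np.zeros(n_tests, dtype=bool)
        for i in range(n_tests):
            d = diffs[i]
            d = d[np.isfinite(d)]
            nz = d[d != 0]
            if nz.size < min_pairs:
                skipped[i] = True
                continue
            p[i] = stats.wilcoxon(nz, alternative="two-sided").pvalue
        tested = ~skipped
        qvals = np.full(n_tests, np.nan)
        mask = np.zeros(n_tests, dtype=bool)
        if tested.any():
            _, qv, _, _ = multipletests(p[tested], alpha=q, method="fdr_bh")
            qvals[tested] = qv
            mask[tested] = bh_mask(p[tested], q)
        out[name] = {"p": p, "q": qvals, "significant": mask, "skipped": skipped}
    return out


def dominance_matrix(
    cgc_xy: np.ndarray,
    cgc_yx: np.ndarray,
    pairs: list,
    n_contacts: int,
    band: str = "",
    q: float = 0.05,
) -> DominanceMatrix:
    """Signed dominance matrix from per-session directional cGCs.

    ``cgc_xy``/``cgc_yx`` are (n_pairs, n_sessions) band-averaged cGCs for
    the two directions of each unordered pair (x, y) in ``pairs``.  Per
    pair, a Wilcoxon signed-rank test on the directional difference is
    BH-corrected within the band; significant pairs receive the
    session-mean strength of the dominant direction, with entry (x, y)
    positive when x->y dominates (and (y, x) the negative mirror).
    """
    cgc_xy = np.atleast_2d(cgc_xy)
    cgc_yx = np.atleast_2d(cgc_yx)
    res = wilcoxon_fdr({band: cgc_xy - cgc_yx}, q=q)[band]
    mat = np.zeros((n_contacts, n_contacts))
    for k, (x, y) in enumerate(pairs):
        if not res["significant"][k]:
            continue
        if cgc_xy[k].mean() >= cgc_yx[k].mean():
            strength = cgc_xy[k].mean()
            mat[x, y] = strength
            mat[y, x] = -strength
        else:
            strength = cgc_yx[k].mean()
            mat[y, x] = strength
            mat[x, y] = -strength
    return DominanceMatrix(band=band, matrix=mat, q=q)


def normalize_cgc(band_values: dict) -> dict:
    """Normalize band-averaged cGCs to their maximum across bands.

    ``band_values`` maps band name to a scalar or array of cGCs for one
    subject group and pool (e.g. one monkey's within-area cGCs averaged
    across sessions); every value is divided by the single maximum over
    all bands, so the maximum maps to 1.  Groups/pools are normalized
    independently by calling this per group.
    """
    peak = max(float(np.max(v)) for v in band_values.values())
    if peak <= 0:
        raise ValueError("cannot normalize: maximum cGC across bands is zero")
    return {b: np.asarray(v, dtype=float) / peak for b, v in band_values.items()}


def compartment_pool(
    values: np.ndarray,
    pairs: list,
    compartment_of: np.ndarray,
) -> np.ndarray:
    """Average directed contact-pair values into a 3x3 compartment matrix.

    Rows index the source compartment, columns the target, in the order
    (supragranular, granular, infragranular); contacts labeled
    "unassigned" are excluded.  Empty cells are NaN and flagged with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    acc = np.zeros((3, 3))
    cnt = np.zeros((3, 3), dtype=int)
    comp_index = {c: i for i, c in enumerate(COMPARTMENTS)}
    for v, (s, t) in zip(values, pairs):
        cs = compartment_of[s]
        ct = compartment_of[t]
        if cs not in comp_index or ct not in comp_index:
            continue
        acc[comp_index[cs], comp_index[ct]] += v
        cnt[comp_index[cs], comp_index[ct]] += 1
    with np.errstate(invalid="ignore"):
        pooled = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    if (cnt == 0).any():
        empties = [(COMPARTMENTS[i], COMPARTMENTS[j])
                   for i, j in zip(*np.nonzero(cnt == 0))]
        warnings.warn(f"empty compartment cells: {empties}", stacklevel=2)
    return pooled


def smi(timefreq_rf: TimeFreqMap, timefreq_out: TimeFreqMap) -> TimeFreqMap:
    """Spectrogram modulation index per (time, frequency, unit) cell.

    Applies :func:`modulation_index` cellwise to two matching
    time-frequency power maps (raw, nonnegative power by default; the
    caller is responsible for not passing signed z-scores unless that is
    intended).
    """
    if (timefreq_rf.values.shape != timefreq_out.values.shape
            or not np.allclose(timefreq_rf.times_ms, timefreq_out.times_ms)
            or not np.allclose(timefreq_rf.freqs, timefreq_out.freqs)):
        raise ValueError("time-frequency grids do not match")
    return TimeFreqMap(
        times_ms=timefreq_rf.times_ms.copy(),
        freqs=timefreq_rf.freqs.copy(),
        values=modulation_index(timefreq_rf.values, timefreq_out.values),
        window_samples=timefreq_rf.window_samples,
        step_ms=timefreq_rf.step_ms,
    )


def repeated_measures_anova(values: np.ndarray) -> float:
    """Single-factor repeated-measures ANOVA p-value across conditions.

    ``values`` is (n_conditions, n_subjects); used as a secondary check on
    the RF/OUT1/OUT2 triplet before pooling the away conditions.
    """
    v = np.asarray(values, dtype=float)
    k, n = v.shape
    grand = v.mean()
    ss_cond = n * ((v.mean(axis=1) - grand) ** 2).sum()
    ss_subj = k * ((v.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((v - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    f = (ss_cond / df_cond) / (ss_err / df_err)
    return float(stats.f.sf(f, df_cond, df_err))
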