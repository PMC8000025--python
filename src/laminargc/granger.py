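"""Multi-trial VAR fitting and conditional spectral Granger causality.

Directed communication between contacts X -> Y given a conditioning set Z
is quantified by Geweke's conditional Granger causality (cGC),
f_{X->Y|Z}(f), computed parametrically from two vector autoregressions:

* the *full* model on (Y, X, Z), with spectral transfer H(f) and
  innovation covariance Sigma;
* the *reduced* model on (Y, Z), with transfer G(f) and covariance
  Sigma_R.

Embedding G^-1 into the full variable space (identity on X) and applying
it to the full transfer — after normalizing the full innovations so Y's
innovation is uncorrelated with the rest — yields Q(f) = G_hat^-1(f)
H_tilde(f), and

    f_{X->Y|Z}(f) = ln( Sigma_R[yy] / ( |Q_yy(f)|^2 Sigma[yy] ) ).

Its average over frequency equals the time-domain conditional GC
ln(Sigma_R[yy] / Sigma[yy]) for well-specified models (Geweke's integral
identity), which the test-suite checks against an analytic oracle.
Negative numerical artifacts are clipped to zero and counted.

VAR models are fitted by multi-trial least squares (per-trial demeaned,
lag-stacked covariances pooled across trials); the order is chosen by BIC
over 1..p_max unless fixed.  Significance thresholds are the 95th
percentile of cGC recomputed with the source channel's trial order
permuted relative to the target (the conditioning set stays with the
target).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VARModel", "GCResult", "fit_var", "var_transfer",
    "conditional_spectral_gc", "time_domain_cgc", "shuffle_null_threshold",
    "pairwise_cgc",
]


@dataclass
class VARModel:
    """Fitted vector autoregression x_t = sum_k A_k x_{t-k} + e_t."""

    order: int
    coefs: np.ndarray            # (order, dim, dim)
    sigma: np.ndarray            # innovation covariance (dim, dim)
    spectral_radius: float
    n_effective: int             # pooled regression rows
    criterion: dict = field(default_factory=dict)   # order -> BIC value

    @property
    def dim(self) -> int:
        return self.sigma.shape[0]


@dataclass
class GCResult:
    """Frequency-resolved conditional GC for directed pairs."""

    freqs: np.ndarray
    pairs: list                   # [(source, target), ...]
    cgc: np.ndarray               # (n_pairs, n_freqs), >= 0
    conditioning: list = field(default_factory=list)
    threshold: Optional[np.ndarray] = None        # per-pair, per-freq null
    band_threshold: Optional[dict] = None         # band -> per-pair null
    window: str = ""
    n_clipped: int = 0


def _demean(epochs: np.ndarray) -> np.ndarray:
    x = np.asarray(epochs, dtype=float)
    if x.ndim == 2:
        x = x[np.newaxis]
    return x - x.mean(axis=-1, keepdims=True)


def _companion_radius(coefs: np.ndarray) -> float:
    p, d, _ = coefs.shape
    comp = np.zeros((p * d, p * d))
    comp[:d] = coefs.transpose(1, 0, 2).reshape(d, p * d)
    if p > 1:
        comp[d:, :-d] = np.eye((p - 1) * d)
    return float(np.abs(np.linalg.eigvals(comp)).max())


def fit_var(
    epochs: np.ndarray,
    order: Optional[int] = None,
    p_max: int = 20,
    guard_ratio: float = 10.0,
    ridge: float = 1e-8,
) -> VARModel:
    """Multi-trial least-squares VAR fit with BIC order selection.

    ``epochs`` is (n_trials, dim, n_samples); each trial is demeaned and
    the lagged design rows of all trials are pooled.  If ``order`` is
    None, BIC is evaluated for orders 1..p_max on a common sample (rows
    starting at lag p_max) and the minimizer is kept.  Errors are raised
    for unstable fits, singular/ill-conditioned covariances (e.g. an
    exactly duplicated channel), and effective sample sizes below
    ``guard_ratio`` * order * dim^2.
    """
    x = _demean(epochs)
    n_trials, d, n = x.shape
    p_hi = order if order is not None else p_max
    if n <= p_hi + 1:
        raise ValueError(f"epochs of {n} samples too short for order {p_hi}")
    # pooled response and lag-stacked design
    y = x[:, :, p_hi:].transpose(0, 2, 1).reshape(-1, d)
    cols = [x[:, :, p_hi - k:n - k].transpose(0, 2, 1).reshape(-1, d)
            for k in range(1, p_hi + 1)]
    xd = np.concatenate(cols, axis=1)
    t_eff = y.shape[0]
    gram = xd.T @ xd
    cross = xd.T @ y
    s0 = y.T @ y

    def _solve(p: int):
        k = d * p
        gp = gram[:k, :k]
        cond = np.linalg.cond(gp)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"singular lag covariance at order {p} (cond={cond:.3g}); "
                "check for duplicated or constant channels"
            )
        beta = np.linalg.solve(gp, cross[:k])
        sig = (s0 - cross[:k].T @ beta) / t_eff
        return beta, 0.5 * (sig + sig.T)

    crit = {}
    if order is None:
        for p in range(1, p_hi + 1):
            try:
                _, sig = _solve(p)
            except np.linalg.LinAlgError:
                continue
            sign, logdet = np.linalg.slogdet(sig)
            if sign <= 0:
                continue
            crit[p] = logdet + np.log(t_eff) * p * d * d / t_eff
        if not crit:
            raise np.linalg.LinAlgError("no admissible VAR order (singular fits)")
        order = min(crit, key=crit.get)
    if t_eff < guard_ratio * order * d * d:
        raise ValueError(
            f"guard ratio violated: {t_eff} pooled samples < "
            f"{guard_ratio:g} * {order} * {d}^2"
        )
    beta, sigma = _solve(order)
    eig = np.linalg.eigvalsh(sigma)
    if eig.min() <= 0:
        sigma = sigma + ridge * np.trace(sigma) / d * np.eye(d)
        warnings.warn("innovation covariance regularized by ridge", stacklevel=2)
        if np.linalg.eigvalsh(sigma).min() <= 0:
            raise np.linalg.LinAlgError("innovation covariance not positive definite")
    coefs = beta.reshape(order, d, d).transpose(0, 2, 1)
    radius = _companion_radius(coefs)
    if radius >= 1.0:
        raise ValueError(f"fitted VAR unstable (spectral radius {radius:.4f})")
    return VARModel(order=order, coefs=coefs, sigma=sigma,
                    spectral_radius=radius, n_effective=t_eff, criterion=crit)


def var_transfer(model: VARModel, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Spectral transfer H(f) = (I - sum_k A_k e^{-2 pi i f k / fs})^-1."""
    d = model.dim
    lags = np.arange(1, model.order + 1)
    phase = np.exp(-2j * np.pi * np.asarray(freqs)[:, None] * lags[None, :] / fs)
    a_f = np.tensordot(phase, model.coefs, axes=(1, 0))
    return np.linalg.inv(np.eye(d)[None] - a_f)


def time_domain_cgc(full: VARModel, reduced: VARModel) -> float:
    """Time-domain conditional GC ln(Sigma_R[yy] / Sigma[yy]).

    Both models must be ordered with the target variable first.
    """
    return float(np.log(reduced.sigma[0, 0] / full.sigma[0, 0]))


def _cgc_spectrum(full: VARModel, reduced: VARModel, freqs: np.ndarray,
                  fs: float) -> np.ndarray:
    """Spectral cGC given the full model on (y, x, z) and reduced on (y, z)."""
    m = full.dim
    ridx = np.array([0] + list(range(2, m)))      # positions of (y, z) in full
    h = var_transfer(full, freqs, fs)
    # decorrelate y's innovation from the rest
    pinv = np.eye(m)
    pinv[1:, 0] = full.sigma[1:, 0] / full.sigma[0, 0]
    h = h @ pinv
    g = var_transfer(reduced, freqs, fs)
    g_embed = np.tile(np.eye(m, dtype=complex), (len(freqs), 1, 1))
    g_embed[:, ridx[:, None], ridx[None, :]] = g
    q = np.linalg.solve(g_embed, h)
    denom = (np.abs(q[:, 0, 0]) ** 2) * full.sigma[0, 0]
    return np.log(reduced.sigma[0, 0] / denom)


def _default_freqs(fs: float, n: int = 512) -> np.ndarray:
    return np.fft.rfftfreq(n, d=1.0 / fs)


def conditional_spectral_gc(
    epochs: np.ndarray,
    source: int,
    target: int,
    conditioning: Sequence[int] = (),
    fs: float = 1017.375,
    freqs: Optional[np.ndarray] = None,
    order: Optional[int] = None,
    p_max: int = 20,
) -> GCResult:
    """Geweke conditional spectral GC from ``source`` to ``target``.

    ``conditioning`` channels must exclude source and target (an empty set
    gives the unconditional bivariate measure).  The full model's BIC
    order (or the fixed ``order``) is reused for the reduced model.
    Values are clipped at zero; the clip count is reported.
    """
    z = list(conditioning)
    if source == target or source in z or target in z:
        raise ValueError("source, target and conditioning set must be disjoint")
    x = _demean(epochs)
    if freqs is None:
        freqs = _default_freqs(fs, x.shape[-1])
    idx = [target, source] + z
    full = fit_var(x[:, idx, :], order=order, p_max=p_max)
    reduced = fit_var(x[:, [target] + z, :], order=full.order)
    spec = _cgc_spectrum(full, reduced, freqs, fs)
    n_clipped = int((spec < 0).sum())
    if n_clipped > 0.01 * spec.size:
        warnings.warn(
            f"{n_clipped}/{spec.size} negative cGC bins clipped", stacklevel=2
        )
    return GCResult(
        freqs=np.asarray(freqs), pairs=[(source, target)],
        cgc=np.clip(spec, 0.0, None)[None, :], conditioning=[tuple(z)],
        n_clipped=n_clipped,
    )


def shuffle_null_threshold(
    epochs: np.ndarray,
    source: int,
    target: int,
    conditioning: Sequence[int] = (),
    fs: float = 1017.375,
    freqs: Optional[np.ndarray] = None,
    order: Optional[int] = None,
    n_shuffles: int = 200,
    percentile: float = 95.0,
    seed: Optional[int] = None,
    bands: Optional[dict] = None,
) -> tuple:
    """Trial-shuffle null threshold for f_{source->target|Z}.

    For each shuffle the source channel's trial order is permuted relative
    to the target (the conditioning set stays with the target) and the
    cGC is recomputed with the same model order; the per-frequency
    ``percentile`` of the null ensemble is returned, together with
    band-averaged percentiles when ``bands`` is given.
    """
    x = _demean(epochs)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 trials to shuffle")
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20 for a stable 95th percentile")
    if n_shuffles < 100:
        warnings.warn(
            f"n_shuffles={n_shuffles} < 100: the 95th percentile is noisy",
            stacklevel=2,
        )
    z = list(conditioning)
    if freqs is None:
        freqs = _default_freqs(fs, x.shape[-1])
    idx = [target, source] + z
    full = fit_var(x[:, idx, :], order=order)
    reduced = fit_var(x[:, [target] + z, :], order=full.order)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, len(freqs)))
    shuf = x[:, idx, :].copy()
    for s in range(n_shuffles):
        perm = rng.permutation(x.shape[0])
        shuf[:, 1, :] = x[perm, source, :]
        full_s = fit_var(shuf, order=full.order)
        null[s] = np.clip(_cgc_spectrum(full_s, reduced, freqs, fs), 0.0, None)
    thr = np.percentile(null, percentile, axis=0)
    band_thr = None
    if bands is not None:
        from .spectral import band_average
        banded = band_average(null, np.asarray(freqs), bands)
        band_thr = {b: float(np.percentile(v, percentile))
                    for b, v in banded.items()}
    return thr, band_thr


def _conditioning_set(channels: np.ndarray, positions: np.ndarray,
                      src: int, tgt: int, cap: int) -> list:
    """Remaining channels, capped to the ``cap`` nearest by depth."""
    rest = [c for c in channels if c not in (src, tgt)]
    if len(rest) <= cap:
        return rest
    mid = (positions[src] + positions[tgt]) / 2.0
    rest.sort(key=lambda c: abs(positions[c] - mid))
    return sorted(rest[:cap])


def pairwise_cgc(
    session,
    scope: str = "within",
    trials: Optional[np.ndarray] = None,
    fs: Optional[float] = None,
    freqs: Optional[np.ndarray] = None,
    order: Optional[int] = None,
    p_max: int = 20,
    conditioning_cap: int = 8,
    n_shuffles: int = 0,
    percentile: float = 95.0,
    seed: Optional[int] = None,
    window: str = "pre_dimming",
) -> GCResult:
    """cGC for every ordered contact pair of a bipolar session.

    ``scope`` "within" iterates ordered pairs inside each probe,
    conditioning on the remaining derivations of that probe; "between"
    iterates pairs across the two probes, conditioning on the remaining
    derivations of both.  The conditioning set is capped to
    ``conditioning_cap`` channels nearest in depth to the pair.  With
    ``n_shuffles`` > 0, per-pair shuffle thresholds are attached.
    """
    fs = fs or session.fs
    lfp = session.lfp if trials is None else session.lfp[trials]
    pos = session.channel_position
    probes = session.probes()
    pair_specs = []
    if scope == "within":
        for probe in probes:
            ch = session.channels(probe)
            for s in ch:
                for t in ch:
                    if s != t:
                        pair_specs.append((s, t, ch))
        pool = None
    elif scope == "between":
        all_ch = np.arange(session.n_channels)
        a, b = session.channels(probes[0]), session.channels(probes[1])
        for s in a:
            for t in b:
                pair_specs.append((s, t, all_ch))
                pair_specs.append((t, s, all_ch))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if freqs is None:
        freqs = _default_freqs(fs, lfp.shape[-1])
    pairs, conds, rows, thrs = [], [], [], []
    n_clipped = 0
    for s, t, chans in pair_specs:
        z = _conditioning_set(chans, pos, s, t, conditioning_cap)
        try:
            res = conditional_spectral_gc(
                lfp, s, t, z, fs=fs, freqs=freqs, order=order, p_max=p_max
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise RuntimeError(f"cGC failed for pair {s}->{t}: {exc}") from exc
        pairs.append((int(s), int(t)))
        conds.append(tuple(int(c) for c in z))
        rows.append(res.cgc[0])
        n_clipped += res.n_clipped
        if n_shuffles:
            thr, _ = shuffle_null_threshold(
                lfp, s, t, z, fs=fs, freqs=freqs, order=order,
                n_shuffles=n_shuffles, percentile=percentile, seed=seed,
            )
            thrs.append(thr)
    return GCResult(
        freqs=np.asarray(freqs), pairs=pairs, cgc=np.vstack(rows),
        conditioning=conds,
        threshold=np.vstack(thrs) if thrs else None,
        window=window, n_clipped=n_clipped,
    )
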