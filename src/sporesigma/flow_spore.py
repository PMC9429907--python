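"""Flow-cytometry spore/vegetative classification and spore-yield statistics.

Cultures are stained with SYBR green, which penetrates vegetative cells but
not spores, so vegetative cells fluoresce brightly and spores dimly.  The
gating pipeline mirrors the standard automated strategy:

1. all channels are asinh-transformed (variance stabilisation),
2. singlets are separated from doublets by a robust line fit of FSC height
   on FSC area (doublets have inflated area at a given height),
3. low-scatter noise events are removed at the deepest density minimum
   below the FSC-area mode,
4. a two-component Gaussian mixture over (FSC area, fluorescence area) is
   trained on the non-induced control of each strain x run, the component
   with higher mean fluorescence labelled vegetative, and
5. the trained model classifies every sample of that strain/run.

Spore yield is the ratio of percent spores in an induced culture to its
paired non-induced control; strain effects are assessed with Welch tests
against the empty-vector control, adjusted across strains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from .stats import (  # noqa: F401  (paired_density_test re-exported)
    WelchResult,
    adjust_pvalues,
    paired_density_test,
    welch_t_test,
)

__all__ = [
    "SporeMixtureModel",
    "SporeCount",
    "SporeYield",
    "asinh_transform",
    "singlet_gate",
    "noise_threshold",
    "noise_gate",
    "fit_spore_mixture",
    "classify_events",
    "spore_yield",
    "summarize_yields",
    "compare_yields",
    "paired_density_test",
]

CHANNELS = ("fsc_h", "fsc_a", "fl_a")


def asinh_transform(
    events: pd.DataFrame, cofactor: float = 1.0, channels: Sequence[str] = CHANNELS
) -> pd.DataFrame:
    """Per-channel x -> asinh(x / cofactor); monotone, order-preserving."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    out = events.copy()
    for ch in channels:
        x = out[ch].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise ValueError(f"non-finite values in channel {ch!r}")
        out[ch] = np.arcsinh(x / cofactor)
    return out


def singlet_gate(events: pd.DataFrame, k: float = 2.5, max_fit_points: int = 2000) -> np.ndarray:
    """Singlet mask from a robust (Theil-Sen) line of fsc_h on fsc_a.

    Keeps events whose residual from the fitted line is within ``k`` robust
    scales (1.4826 x MAD).  Doublets — inflated area at singlet height —
    fall below the line and are cut.  The Theil-Sen fit is quadratic in the
    number of points, so it runs on at most ``max_fit_points`` events chosen
    evenly along the sorted (fsc_a, fsc_h) order (deterministic and
    invariant to event order); the residual band applies to all events.
    """
    if len(events) < 50:
        raise ValueError("singlet gate needs >= 50 events for a stable fit")
    x = events["fsc_a"].to_numpy(dtype=float)
    y = events["fsc_h"].to_numpy(dtype=float)
    if len(x) > max_fit_points:
        order = np.lexsort((y, x))
        idx = order[np.linspace(0, len(x) - 1, max_fit_points).astype(int)]
        xs, ys = x[idx], y[idx]
    else:
        xs, ys = x, y
    slope, intercept, _, _ = sps.theilslopes(ys, xs)
    resid = y - (intercept + slope * x)
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if scale == 0:
        scale = np.finfo(float).tiny
    return np.abs(resid - np.median(resid)) <= k * scale


def noise_threshold(
    values: np.ndarray, fallback_quantile: float | None = 0.005
) -> float | None:
    """Low-end cut on transformed FSC area separating noise from cells.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a grid; the
    threshold is the deepest density minimum below the global mode.  With a
    unimodal low tail and ``fallback_quantile`` set, that quantile is used;
    with the fallback disabled, None is returned (retain everything).
    """
    v = np.asarray(values, dtype=float)
    kde = sps.gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(v.min(), v.max(), 512)
    dens = kde(grid)
    mode_i = int(np.argmax(dens))
    # local minima strictly below the global mode
    d = dens[: mode_i + 1]
    minima = [
        i for i in range(1, len(d) - 1) if d[i] <= d[i - 1] and d[i] < d[i + 1]
    ]
    if minima:
        deepest = min(minima, key=lambda i: d[i])
        return float(grid[deepest])
    if fallback_quantile is not None:
        return float(np.quantile(v, fallback_quantile))
    return None


def noise_gate(
    events: pd.DataFrame, fallback_quantile: float | None = 0.005
) -> np.ndarray:
    """Mask retaining events above the low-FSC-area noise threshold."""
    v = events["fsc_a"].to_numpy(dtype=float)
    thr = noise_threshold(v, fallback_quantile)
    if thr is None:
        import warnings

        warnings.warn("no density minimum and fallback disabled: retaining all events")
        return np.ones(len(v), dtype=bool)
    return v > thr


@dataclass
class SporeMixtureModel:
    """Two-component Gaussian mixture over transformed (fsc_a, fl_a).

    The component with the higher mean fluorescence is vegetative (SYBR
    green enters vegetative cells, not spores).
    """

    mixture: GaussianMixture
    spore_component: int
    strain: str
    run: str

    @property
    def weights(self) -> np.ndarray:
        return self.mixture.weights_

    @property
    def means(self) -> np.ndarray:
        return self.mixture.means_

    @property
    def spore_weight(self) -> float:
        return float(self.mixture.weights_[self.spore_component])


@dataclass(frozen=True)
class SporeCount:
    n_spores: int
    n_vegetative: int

    @property
    def n_total_gated(self) -> int:
        return self.n_spores + self.n_vegetative

    @property
    def pct_spores(self) -> float:
        if self.n_total_gated == 0:
            raise ValueError("no gated events: percent spores undefined")
        return 100.0 * self.n_spores / self.n_total_gated


@dataclass(frozen=True)
class SporeYield:
    """Per-pair induced/control yields aggregated to a clone-level mean."""

    pair_yields: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.pair_yields))

    @property
    def sem(self) -> float:
        y = np.asarray(self.pair_yields)
        return float(y.std(ddof=1) / np.sqrt(y.size)) if y.size > 1 else float("nan")


def fit_spore_mixture(
    control_events_gated: pd.DataFrame,
    strain: str,
    run: str,
    n_restarts: int = 5,
    seed: int = 0,
    min_events: int = 1000,
) -> SporeMixtureModel:
    """EM fit of the two-population model on a gated, transformed control.

    ``n_restarts`` seeded initialisations are run and the best
    log-likelihood kept.  Components are labelled by mean fluorescence; a
    component weight below 0.1% triggers a degenerate-split warning.
    """
    if len(control_events_gated) < min_events:
        raise ValueError(
            f"mixture training needs >= {min_events} gated events, got {len(control_events_gated)}"
        )
    X = control_events_gated[["fsc_a", "fl_a"]].to_numpy(dtype=float)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_restarts,
        random_state=seed,
        reg_covar=1e-6,
    )
    gm.fit(X)
    if not gm.converged_:
        raise RuntimeError("EM failed to converge after restarts")
    if np.min(gm.weights_) < 1e-3:
        import warnings

        warnings.warn("degenerate mixture split: a component weight is below 0.1%")
    spore_component = int(np.argmin(gm.means_[:, 1]))  # low fluorescence = spores
    return SporeMixtureModel(mixture=gm, spore_component=spore_component, strain=strain, run=run)


def classify_events(
    model: SporeMixtureModel,
    sample_events_gated: pd.DataFrame,
    strain: str | None = None,
    run: str | None = None,
    override: bool = False,
) -> SporeCount:
    """Maximum-posterior spore/vegetative assignment of gated events."""
    if len(sample_events_gated) == 0:
        raise ValueError("empty event set: nothing to classify")
    if not override:
        if strain is not None and strain != model.strain:
            raise ValueError(f"model trained on strain {model.strain!r}, sample is {strain!r}")
        if run is not None and run != model.run:
            raise ValueError(f"model trained on run {model.run!r}, sample is {run!r}")
    X = sample_events_gated[["fsc_a", "fl_a"]].to_numpy(dtype=float)
    labels = model.mixture.predict(X)
    n_spores = int(np.sum(labels == model.spore_component))
    return SporeCount(n_spores=n_spores, n_vegetative=len(labels) - n_spores)


def spore_yield(induced: SporeCount, control: SporeCount) -> float:
    """pct_spores(induced) / pct_spores(control) for one sample pair."""
    pct_control = control.pct_spores
    if pct_control == 0:
        raise ValueError("control has zero percent spores: yield undefined")
    return induced.pct_spores / pct_control


def summarize_yields(pairs: Sequence[tuple[SporeCount, SporeCount]]) -> SporeYield:
    """Aggregate per-pair yields to a clone-level mean +/- SEM."""
    return SporeYield(pair_yields=tuple(spore_yield(i, c) for i, c in pairs))


def compare_yields(
    strain_yields: Mapping[str, Sequence[float]],
    empty_vector_yields: Sequence[float],
    adjust: str = "holm",
) -> pd.DataFrame:
    """Welch test of each strain's clone yields against the empty vector.

    Returns one row per strain with t, df, raw p and p adjusted across
    strains (Holm by default; 'bh' and 'by' selectable).
    """
    strains = list(strain_yields)
    rows = []
    for s in strains:
        r = welch_t_test(strain_yields[s], empty_vector_yields)
        rows.append((s, r.t, r.df, r.p, r.mean_a, r.n_a))
    df = pd.DataFrame(rows, columns=["strain", "t", "df", "p", "mean_yield", "n"])
    df["p_adj"] = adjust_pvalues(df["p"].to_numpy(), method=adjust)
    return df


def gate_events(
    raw_events: pd.DataFrame,
    cofactor: float = 1.0,
    singlet_k: float = 2.5,
    noise_fallback_quantile: float | None = 0.005,
) -> pd.DataFrame:
    """Full pre-model gating: asinh transform, singlet gate, then noise gate."""
    t = asinh_transform(raw_events, cofactor=cofactor)
    singlets = t[singlet_gate(t, k=singlet_k)]
    return singlets[noise_gate(singlets, fallback_quantile=noise_fallback_quantile)]
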