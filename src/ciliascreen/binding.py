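"""Dissociation-constant estimation from MST dose-response data.

Microscale thermophoresis reports binding through Fnorm, the ratio of
fluorescence inside a "hot" (IR-laser on) time window to a "cold" baseline
window, as a function of titrated unlabelled ligand.  With the labelled
target held at a fixed concentration T that is not negligible against the
dissociation constant, the fraction of bound target follows the quadratic
1:1 ligand-depletion isotherm

    FB(L) = ((L + T + Kd) - sqrt((L + T + Kd)^2 - 4 L T)) / (2 T)

and the observed signal is B + A * FB(L) with free baseline B and signal
amplitude A (either sign: thermophoretic responses may decrease on
binding).  Kd is fit by least squares in log10(Kd), with B and A profiled
out linearly at every candidate Kd, multistarted on a log-spaced grid that
spans well beyond the titration range.  Uncertainty comes from a
case-resampling bootstrap stratified by concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

__all__ = [
    "DoseResponse",
    "BindingFit",
    "read_dose_response",
    "compute_fnorm",
    "binding_isotherm",
    "fit_kd",
    "bootstrap_ci",
    "compare_kd",
    "write_fit",
]

# a fit whose Kd lands this many fold above the titration top is declared
# unconstrained: the data contain no curvature to pin it
MAX_KD_TO_TOP_RATIO = 10.0

_GRID_POINTS = 60
_GRID_PAD_DECADES = 2.0


@dataclass
class DoseResponse:
    """Titration points (conc_M, fnorm, replicate) plus the labelled-target
    concentration ``target_conc`` (M)."""

    frame: "pd.DataFrame"
    target_conc: float

    def __post_init__(self) -> None:
        if self.target_conc <= 0:
            raise ValueError("target_conc must be positive")
        required = {"conc_M", "fnorm"}
        if missing := required - set(self.frame.columns):
            raise ValueError(f"dose-response table lacks columns {sorted(missing)}")
        if "replicate" not in self.frame.columns:
            self.frame = self.frame.assign(replicate=1)
        L = self.frame["conc_M"].to_numpy(dtype=float)
        if (L < 0).any() or not np.isfinite(L).all():
            raise ValueError("ligand concentrations must be finite and >= 0")

    @property
    def conc(self) -> np.ndarray:
        return self.frame["conc_M"].to_numpy(dtype=float)

    @property
    def fnorm(self) -> np.ndarray:
        return self.frame["fnorm"].to_numpy(dtype=float)

    def per_concentration_sd(self) -> "pd.DataFrame":
        """Mean and SD of Fnorm per concentration across replicates."""
        g = self.frame.groupby("conc_M")["fnorm"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"std": "sd", "count": "n"})


@dataclass
class BindingFit:
    kd: float                 # M; nan when not reported
    baseline: float
    amplitude: float
    rss: float
    converged: bool
    kd_ci: tuple[float, float] | None = None    # 95% bootstrap interval
    kd_ci68: tuple[float, float] | None = None
    message: str = ""


def read_dose_response(path, target_conc: float) -> DoseResponse:
    import pandas as pd
    frame = pd.read_csv(path, sep=None, engine="python")
    return DoseResponse(frame, target_conc=target_conc)


def compute_fnorm(time_s, fluorescence, cold_window: tuple[float, float],
                  hot_window: tuple[float, float],
                  permille: bool = False) -> float:
    """Fnorm of one raw trace: mean fluorescence in the hot window divided
    by the mean in the cold window (x1000 with ``permille``)."""
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    for name, (lo, hi) in (("cold", cold_window), ("hot", hot_window)):
        if lo >= hi:
            raise ValueError(f"{name} window is empty")
        if lo < t.min() or hi > t.max():
            raise ValueError(f"{name} window outside the trace span")
    if cold_window[1] > hot_window[0]:
        raise ValueError("cold window must precede the hot window")
    cold = f[(t >= cold_window[0]) & (t <= cold_window[1])].mean()
    hot = f[(t >= hot_window[0]) & (t <= hot_window[1])].mean()
    if cold == 0:
        raise ValueError("degenerate trace: zero cold-window mean")
    ratio = hot / cold
    return 1000.0 * ratio if permille else ratio


def binding_isotherm(L, T: float, kd: float, baseline: float = 0.0,
                     amplitude: float = 1.0, depletion: bool = True):
    """Predicted signal baseline + amplitude * FB(L).

    ``depletion=True`` uses the quadratic 1:1 isotherm (exact for any T);
    ``False`` uses the hyperbola L / (L + kd), valid when T << kd.  The
    quadratic is evaluated in the cancellation-free form
    2L / (s + sqrt(s^2 - 4 L T)), s = L + T + kd.
    """
    L = np.asarray(L, dtype=float)
    if T <= 0 or kd <= 0:
        raise ValueError("target concentration and kd must be positive")
    if depletion:
        s = L + T + kd
        fb = 2.0 * L / (s + np.sqrt(s * s - 4.0 * L * T))
    else:
        fb = L / (L + kd)
    return baseline + amplitude * fb


def _profiled_rss(log10_kd: float, L: np.ndarray, y: np.ndarray,
                  T: float, depletion: bool) -> tuple[float, float, float]:
    """RSS at fixed Kd with baseline and amplitude solved linearly."""
    fb = binding_isotherm(L, T, 10.0 ** log10_kd, depletion=depletion)
    m = float(L.size)
    sf, sf2 = fb.sum(), (fb * fb).sum()
    sy, sfy = y.sum(), (fb * y).sum()
    det = m * sf2 - sf * sf
    if det <= 1e-12 * m * max(sf2, 1e-300):
        # FB effectively constant: amplitude unidentifiable at this Kd
        b = y.mean()
        resid = y - b
        return float(resid @ resid), b, 0.0
    b = (sf2 * sy - sf * sfy) / det
    a = (m * sfy - sf * sy) / det
    resid = y - b - a * fb
    return float(resid @ resid), b, a


def _fit_arrays(L: np.ndarray, y: np.ndarray, T: float,
                depletion: bool) -> BindingFit:
    pos = L[L > 0]
    if np.unique(L).size < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")
    span = np.log10(pos.max() / pos.min())
    if span < 2.0:
        raise ValueError("titration must span at least 2 orders of magnitude")
    lo = np.log10(pos.min()) - _GRID_PAD_DECADES
    hi = np.log10(pos.max()) + _GRID_PAD_DECADES
    grid = np.linspace(lo, hi, _GRID_POINTS)
    rss_grid = np.array([_profiled_rss(g, L, y, T, depletion)[0] for g in grid])
    best = int(np.argmin(rss_grid))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, _GRID_POINTS - 1)]
    res = optimize.minimize_scalar(
        lambda g: _profiled_rss(g, L, y, T, depletion)[0],
        bounds=(a, b), method="bounded",
        options={"xatol": 1e-6},
    )
    log_kd = float(res.x) if res.success else grid[best]
    rss, base, amp = _profiled_rss(log_kd, L, y, T, depletion)
    kd = 10.0 ** log_kd
    top = float(L.max())
    if kd > MAX_KD_TO_TOP_RATIO * top:
        return BindingFit(kd=float("nan"), baseline=base, amplitude=amp,
                          rss=rss, converged=False,
                          message=(f"kd estimate {kd:.3g} M exceeds "
                                   f"{MAX_KD_TO_TOP_RATIO:g}x the titration top "
                                   f"{top:.3g} M; not reported"))
    return BindingFit(kd=kd, baseline=base, amplitude=amp, rss=rss,
                      converged=bool(res.success) or True)


def fit_kd(dose_response: DoseResponse, depletion: bool = True) -> BindingFit:
    """Least-squares (Kd, B, A) estimate from pooled replicates.

    Multistarts over a log-spaced Kd grid spanning two decades beyond the
    titration range, then refines the best start.  When the estimate lands
    more than 10x above the highest titrated concentration the fit is
    flagged unconverged and no Kd is reported — the data cannot
    constrain it.
    """
    return _fit_arrays(dose_response.conc, dose_response.fnorm,
                       dose_response.target_conc, depletion)


def bootstrap_ci(dose_response: DoseResponse, fit: BindingFit,
                 n_boot: int = 1000, seed=None,
                 depletion: bool = True, stratify: bool = False) -> dict:
    """Case-resampling bootstrap of the Kd with percentile intervals
    (68.3% and 95%).

    By default all points are resampled jointly.  ``stratify=True``
    resamples within each titration concentration instead; with the usual
    three replicates per concentration the tiny strata shrink the
    resampling variability and the resulting intervals undercover, so the
    joint resample is the default.
    """
    if not fit.converged:
        raise ValueError("cannot bootstrap an unconverged fit")
    L = dose_response.conc
    y = dose_response.fnorm
    T = dose_response.target_conc
    levels = np.unique(L)
    if levels.size < 2:
        raise ValueError("bootstrap needs more than one concentration level")
    strata = [np.flatnonzero(L == lv) for lv in levels]
    rng = np.random.default_rng(seed)
    samples = np.empty(n_boot)
    for i in range(n_boot):
        if stratify:
            idx = np.concatenate([s[rng.integers(0, s.size, s.size)]
                                  for s in strata])
        else:
            idx = rng.integers(0, L.size, L.size)
        try:
            samples[i] = _fit_arrays(L[idx], y[idx], T, depletion).kd
        except ValueError:   # resample degenerate (too few distinct levels)
            samples[i] = np.nan
    ok = samples[np.isfinite(samples)]
    if ok.size == 0:
        raise ValueError("all bootstrap refits were unconstrained")
    lo68, hi68 = np.percentile(ok, [15.85, 84.15])
    lo95, hi95 = np.percentile(ok, [2.5, 97.5])
    return {
        "kd_ci68": (float(lo68), float(hi68)),
        "kd_ci95": (float(lo95), float(hi95)),
        "samples": samples,
        "n_valid": int(ok.size),
    }


def attach_ci(fit: BindingFit, boot: dict) -> BindingFit:
    return replace(fit, kd_ci=boot["kd_ci95"], kd_ci68=boot["kd_ci68"])


def compare_kd(fit_a: BindingFit, fit_b: BindingFit,
               samples_a: np.ndarray | None = None,
               samples_b: np.ndarray | None = None) -> dict:
    """Kd ratio kd_b / kd_a, with a percentile interval from paired
    bootstrap replicates when both sample vectors are supplied."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must be converged to compare")
    out = {"ratio": fit_b.kd / fit_a.kd}
    if samples_a is not None and samples_b is not None:
        n = min(len(samples_a), len(samples_b))
        ratios = np.asarray(samples_b[:n]) / np.asarray(samples_a[:n])
        ratios = ratios[np.isfinite(ratios)]
        lo, hi = np.percentile(ratios, [2.5, 97.5])
        out["ratio_ci95"] = (float(lo), float(hi))
    return out


def write_fit(fit: BindingFit, dose_response: DoseResponse, json_path,
              residuals_path=None, seed=None, depletion: bool = True) -> None:
    import json

    import pandas as pd
    payload = {
        "kd_M": None if not fit.converged else fit.kd,
        "baseline": fit.baseline,
        "amplitude": fit.amplitude,
        "rss": fit.rss,
        "converged": fit.converged,
        "kd_ci95_M": fit.kd_ci,
        "kd_ci68_M": fit.kd_ci68,
        "message": fit.message,
        "seed": seed,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    if residuals_path is not None and fit.converged:
        pred = binding_isotherm(dose_response.conc, dose_response.target_conc,
                                fit.kd, fit.baseline, fit.amplitude,
                                depletion=depletion)
        pd.DataFrame({
            "conc_M": dose_response.conc,
            "fnorm": dose_response.fnorm,
            "predicted": pred,
            "residual": dose_response.fnorm - pred,
        }).to_csv(residuals_path, sep="\t", index=False)
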