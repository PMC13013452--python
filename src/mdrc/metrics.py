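"""Frequency-resolved metrics of distribution components.

A component's axisymmetric tensor evaluated at angular frequency omega gives
the standard shape metrics

    D_iso(omega)    = (D_par(omega) + 2 D_perp(omega)) / 3
    D_delta(omega)  = (D_par(omega) - D_perp(omega)) / (3 D_iso(omega))
    D_delta^2(omega)                                      (squared anisotropy)

and the restriction measures over the probed frequency window
[omega_min, omega_max],

    Delta_{omega/2pi} D_iso    = [D_iso(omega_max) - D_iso(omega_min)]
                                 / [(omega_max - omega_min) / 2pi]
    Delta_{omega/2pi} D_delta^2  analogously,

i.e., the change per Hz of frequency; nonnegative for D_iso under Lorentzian
dispersion, high where diffusion is restricted (dense cell layers).

Evaluation frequencies are conventionally chosen as percentiles of the
protocol's centroid frequencies (10/50/90 by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .forward import IDX, lorentzian_eigenvalue

TWO_PI = 2.0 * np.pi

#: column names of an evaluated-component table
EVAL_COLUMNS = ("w", "D_par_w", "D_perp_w", "theta", "phi", "R1", "R2",
                "D_iso", "D_delta", "D_delta_sq", "delta_diso", "delta_ddsq")


def percentile_frequencies(protocol, percentiles=(10, 50, 90)) -> np.ndarray:
    """Linear-interpolation percentiles of the protocol's centroid
    frequencies, in rad/s."""
    percentiles = np.atleast_1d(percentiles)
    if np.any((percentiles < 0) | (percentiles > 100)):
        raise ValueError("percentiles must lie in [0, 100]")
    if len(protocol) == 0:
        raise ValueError("empty protocol")
    return np.percentile(protocol.omega, percentiles, method="linear")


def eigenvalues_at(params: np.ndarray, omega: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(D_par(omega), D_perp(omega)) for each component row."""
    params = np.atleast_2d(np.asarray(params, dtype=float))
    d_par = lorentzian_eigenvalue(params[:, IDX["D0"]], params[:, IDX["D_par"]],
                                  params[:, IDX["Gamma_par"]], omega)
    d_perp = lorentzian_eigenvalue(params[:, IDX["D0"]],
                                   params[:, IDX["D_perp"]],
                                   params[:, IDX["Gamma_perp"]], omega)
    return d_par, d_perp


def shape_metrics(params: np.ndarray, omega: float) -> dict[str, np.ndarray]:
    """D_iso, D_delta, D_delta_sq of each component at omega."""
    d_par, d_perp = eigenvalues_at(params, omega)
    d_iso = (d_par + 2.0 * d_perp) / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        d_delta = np.where(d_iso > 0, (d_par - d_perp) / (3.0 * d_iso), 0.0)
    return {"D_par_w": d_par, "D_perp_w": d_perp, "D_iso": d_iso,
            "D_delta": d_delta, "D_delta_sq": d_delta ** 2}


def restriction_measures(params: np.ndarray, omega_min: float,
                         omega_max: float) -> tuple[np.ndarray, np.ndarray]:
    """(Delta_{omega/2pi} D_iso, Delta_{omega/2pi} D_delta^2) per component
    over the window [omega_min, omega_max] (rad/s)."""
    if not omega_max > omega_min >= 0:
        raise ValueError("need omega_max > omega_min >= 0")
    lo = shape_metrics(params, omega_min)
    hi = shape_metrics(params, omega_max)
    dnu = (omega_max - omega_min) / TWO_PI
    return ((hi["D_iso"] - lo["D_iso"]) / dnu,
            (hi["D_delta_sq"] - lo["D_delta_sq"]) / dnu)


def evaluate_ensemble(ensemble, omega: float,
                      window: tuple[float, float] | None = None
                      ) -> pd.DataFrame:
    """Pool an ensemble's solutions and evaluate every component at omega.

    Returns a tidy table with one row per pooled component: weight, the
    omega-evaluated eigenvalues and shape metrics, relaxation rates, the
    restriction measures over ``window`` (defaults to (omega/2, 2*omega) if
    not given — callers normally pass the protocol's frequency window), and
    bookkeeping columns ``solution`` (bootstrap index) and ``component``.
    """
    params, weights, sol_idx = ensemble.pooled()
    if window is None:
        window = (omega / 2.0, omega * 2.0)
    out = {"w": weights,
           "theta": params[:, IDX["theta"]] if params.size else np.empty(0),
           "phi": params[:, IDX["phi"]] if params.size else np.empty(0),
           "R1": params[:, IDX["R1"]] if params.size else np.empty(0),
           "R2": params[:, IDX["R2"]] if params.size else np.empty(0)}
    if params.size:
        out.update(shape_metrics(params, omega))
        delta_diso, delta_ddsq = restriction_measures(params, *window)
    else:
        out.update({k: np.empty(0) for k in
                    ("D_par_w", "D_perp_w", "D_iso", "D_delta", "D_delta_sq")})
        delta_diso = delta_ddsq = np.empty(0)
    out["delta_diso"] = delta_diso
    out["delta_ddsq"] = delta_ddsq
    out["solution"] = sol_idx
    out["component"] = np.arange(len(weights))
    df = pd.DataFrame(out)
    df.attrs["omega"] = float(omega)
    df.attrs["window"] = (float(window[0]), float(window[1]))
    df.attrs["S0"] = float(ensemble.S0)
    df.attrs["n_solutions"] = len(ensemble.solutions)
    df.attrs["voxel_index"] = tuple(ensemble.voxel_index)
    return df


def evaluate_collection(ensembles: dict, omega: float,
                        window: tuple[float, float]) -> pd.DataFrame:
    """Evaluate every voxel's ensemble; rows carry (i, j, k) voxel columns
    plus per-voxel ``S0`` and ``n_solutions`` for the fraction algebra."""
    frames = []
    for ix, ens in ensembles.items():
        df = evaluate_ensemble(ens, omega, window)
        df["i"], df["j"], df["k"] = ix
        df["S0"] = ens.S0
        df["n_solutions"] = len(ens.solutions)
        frames.append(df)
    if not frames:
        raise ValueError("no ensembles to evaluate")
    out = pd.concat(frames, ignore_index=True)
    out.attrs["omega"] = float(omega)
    out.attrs["window"] = (float(window[0]), float(window[1]))
    return out
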