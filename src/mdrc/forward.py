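"""Forward signal model for b(omega)-tau_R-tau_E encoding.

Each distribution component is an axisymmetric, frequency-dispersive
diffusion tensor with longitudinal/transverse relaxation rates.  The
eigenvalues disperse from their long-time values D_par / D_perp up toward the
high-frequency diffusivity D_0 through a Lorentzian transition with corner
frequencies Gamma_par / Gamma_perp (rad/s):

    D(omega) = D_0 - (D_0 - D_limit) / (1 + (omega / Gamma)^2)

The measured signal is a weighted sum over components,

    S = sum_i w_i exp(-<b : D_i(omega_cent)>) [1 - exp(-tau_R R1_i)]
        exp(-tau_E R2_i)

where the encoding-tensor contraction is evaluated at the row's centroid
frequency (centroid-kernel approximation; a discretized per-row encoding
spectrum can be supplied instead, see :func:`signal`).

Components are stored as plain float arrays of shape ``(n, 9)`` with the
column order in :data:`COLUMNS`; weights travel separately.
"""

from __future__ import annotations

import numpy as np

#: column order of a component parameter matrix
COLUMNS = ("D_par", "D_perp", "theta", "phi", "D0",
           "Gamma_par", "Gamma_perp", "R1", "R2")
IDX = {name: i for i, name in enumerate(COLUMNS)}


def lorentzian_eigenvalue(D0, D_limit, Gamma, omega):
    """Frequency-dependent eigenvalue D(omega) of the Lorentzian transition.

    Monotonically non-decreasing in omega; D(0) = D_limit, D(inf) = D0.
    Broadcasts over array arguments.
    """
    D0, D_limit, Gamma, omega = map(np.asarray, (D0, D_limit, Gamma, omega))
    if np.any(Gamma <= 0):
        raise ValueError("Gamma must be > 0")
    return D0 - (D0 - D_limit) / (1.0 + (omega / Gamma) ** 2)


def btensor_from_params(b: float, b_delta: float, theta: float,
                        phi: float) -> np.ndarray:
    """3x3 axisymmetric encoding tensor with trace b and shape b_delta.

    Eigenvalues are (b/3)(1 + 2 b_delta) along the (theta, phi) axis and
    (b/3)(1 - b_delta) across it.
    """
    if b < 0:
        raise ValueError("b must be >= 0")
    if not -0.5 <= b_delta <= 1.0:
        raise ValueError(f"b_delta must be in [-0.5, 1], got {b_delta}")
    lam_par = b / 3.0 * (1.0 + 2.0 * b_delta)
    lam_perp = b / 3.0 * (1.0 - b_delta)
    return _axisymmetric_tensor(lam_par, lam_perp, theta, phi)


def _axisymmetric_tensor(lam_par, lam_perp, theta, phi) -> np.ndarray:
    u = _axis(theta, phi)
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(u, u)


def _axis(theta, phi):
    """Unit vector at polar angle theta from +z, azimuth phi from +x."""
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def component_tensor(component: np.ndarray, omega: float) -> np.ndarray:
    """3x3 diffusion tensor of one component row evaluated at omega."""
    c = np.asarray(component, dtype=float).ravel()
    d_par = lorentzian_eigenvalue(c[IDX["D0"]], c[IDX["D_par"]],
                                  c[IDX["Gamma_par"]], omega)
    d_perp = lorentzian_eigenvalue(c[IDX["D0"]], c[IDX["D_perp"]],
                                   c[IDX["Gamma_perp"]], omega)
    return _axisymmetric_tensor(d_par, d_perp, c[IDX["theta"]], c[IDX["phi"]])


def design_matrix(params: np.ndarray, protocol) -> np.ndarray:
    """Kernel matrix K with K[m, i] the signal of unit-weight component i
    under acquisition row m.

    Uses the closed-form contraction of two axisymmetric tensors,
    <b : D> = b * D_iso * (1 + 2 b_delta * D_delta * P2(cos beta)),
    with beta the angle between the encoding and tensor symmetry axes and
    P2 the second Legendre polynomial, evaluated at the row's centroid
    frequency.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    if params.shape[0] == 0:
        raise ValueError("need at least one component")

    omega = protocol.omega[:, None]                    # (m, 1)
    d_par = lorentzian_eigenvalue(params[:, IDX["D0"]], params[:, IDX["D_par"]],
                                  params[:, IDX["Gamma_par"]], omega)
    d_perp = lorentzian_eigenvalue(params[:, IDX["D0"]], params[:, IDX["D_perp"]],
                                   params[:, IDX["Gamma_perp"]], omega)
    d_iso = (d_par + 2.0 * d_perp) / 3.0               # (m, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_delta = np.where(d_iso > 0, (d_par - d_perp) / (3.0 * d_iso), 0.0)

    cos_beta = (np.cos(protocol.theta)[:, None] * np.cos(params[:, IDX["theta"]])
                + np.sin(protocol.theta)[:, None] * np.sin(params[:, IDX["theta"]])
                * np.cos(protocol.phi[:, None] - params[:, IDX["phi"]]))
    p2 = 0.5 * (3.0 * cos_beta ** 2 - 1.0)

    b_dot_d = (protocol.b[:, None] * d_iso
               * (1.0 + 2.0 * protocol.b_delta[:, None] * d_delta * p2))
    relax = ((1.0 - np.exp(-protocol.tau_r[:, None] * params[:, IDX["R1"]]))
             * np.exp(-protocol.tau_e[:, None] * params[:, IDX["R2"]]))
    return np.exp(-b_dot_d) * relax


def signal(params: np.ndarray, weights, protocol,
           spectra: list[tuple[np.ndarray, np.ndarray]] | None = None
           ) -> np.ndarray:
    """Noiseless signals of a weighted component set under a protocol.

    Parameters
    ----------
    params : (n, 9) array
        Component parameter matrix (:data:`COLUMNS` order).
    weights : (n,) array
        Non-negative component weights (signal units).
    protocol : Protocol
    spectra : optional list, one entry per row
        Discretized encoding spectrum ``(omega_j [rad/s], btensors (j,3,3))``
        replacing the centroid-kernel contraction for that row; the b-tensor
        traces must sum to the row's b.

    Returns
    -------
    (n_rows,) array of signals.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    if params.shape[0] == 0:
        raise ValueError("need at least one component")
    if spectra is None:
        return design_matrix(params, protocol) @ weights
    out = np.empty(len(protocol))
    for m in range(len(protocol)):
        omegas, btensors = spectra[m]
        total = 0.0
        for i, c in enumerate(params):
            bdotd = sum(float(np.tensordot(bt, component_tensor(c, om)))
                        for om, bt in zip(omegas, btensors))
            total += (weights[i] * np.exp(-bdotd)
                      * (1 - np.exp(-protocol.tau_r[m] * c[IDX["R1"]]))
                      * np.exp(-protocol.tau_e[m] * c[IDX["R2"]]))
        out[m] = total
    return out


def add_noise(signals: np.ndarray, snr: float, kind: str = "rician",
              seed=None, s0_ref: float | None = None) -> np.ndarray:
    """Add measurement noise at a given signal-to-noise ratio.

    The noise standard deviation is ``s0_ref / snr`` with ``s0_ref`` the
    maximum noiseless signal (overridable).  Rician noise emulates magnitude
    reconstruction: sqrt((S + n1)^2 + n2^2) with independent Gaussian n1, n2.
    ``snr=inf`` returns the input unchanged.
    """
    signals = np.asarray(signals, dtype=float)
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if np.isinf(snr):
        return signals.copy()
    rng = np.random.default_rng(seed)
    sigma = (s0_ref if s0_ref is not None else float(np.max(signals))) / snr
    if kind == "gaussian":
        return signals + rng.normal(0.0, sigma, size=signals.shape)
    if kind == "rician":
        n1 = rng.normal(0.0, sigma, size=signals.shape)
        n2 = rng.normal(0.0, sigma, size=signals.shape)
        return np.sqrt((signals + n1) ** 2 + n2 ** 2)
    raise ValueError(f"unknown noise kind {kind!r}")
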