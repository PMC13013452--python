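"""Synthetic protocols and tissue phantoms.

No acquisitions are distributed with the method, so every stage is exercised
against synthetic ground truth: acquisition protocols drawn within the
printed ranges of the three experiments (ex vivo rat 11.7 T, in vivo rat
7 T, in vivo human 3 T), and image phantoms whose voxels contain known
component mixtures drawn from four tissue archetypes:

``wm_like``
    anisotropic, slow, coherently oriented, fast relaxation — white matter.
``gm_like``
    near-isotropic, slow, no dispersion in the probed window — gray matter.
``fw_like``
    isotropic and fast (D_iso > 1e-9 m^2/s), slow relaxation — free water.
``restricted_like``
    slow at low frequency but dispersing strongly inside the probed window
    (corner frequency ~48 Hz), emulating dense cell layers such as the
    granule cell layer of the dentate gyrus.

Preset centers echo reported tissue values (tissue D_iso mode
~0.27e-9 m^2/s, free water above 1e-9 m^2/s ex vivo at 18 degC) but are
configuration, not measured truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .acquisition import Protocol, TWO_PI
from .forward import IDX, add_noise, signal
from .inversion import _enforce_d0

# ------------------------------------------------------------------ protocols

#: printed acquisition ranges per experiment (SI; omega entries in Hz)
PROTOCOL_PRESETS = {
    "exvivo_rat": dict(b=(0.038e9, 7.13e9), omega_hz=(29.0, 110.0),
                       b_delta=(-0.5, 0.0, 0.5, 1.0),
                       tau_r=(0.2, 7.0), tau_e=(0.006, 0.180)),
    "invivo_rat": dict(b=(0.031e9, 2.65e9), omega_hz=(18.0, 92.0),
                       b_delta=(-0.5, 0.0, 0.5, 1.0),
                       tau_r=(1.0, 3.5), tau_e=(0.021, 0.077)),
    "invivo_human": dict(b=(0.01e9, 3.0e9), omega_hz=(4.0, 9.0),
                         b_delta=(-0.5, 0.0, 1.0),
                         tau_r=(0.62, 7.0), tau_e=(0.040, 0.150)),
}
PROTOCOL_PRESETS["minimal"] = PROTOCOL_PRESETS["exvivo_rat"]

N_ANCHOR_ROWS = 8  # low-b, long-tau_R, short-tau_E rows pinning S0


def make_protocol(preset: str = "minimal", n_rows: int = 150,
                  seed: int = 0) -> Protocol:
    """Randomized protocol within a preset's printed parameter ranges.

    The first :data:`N_ANCHOR_ROWS` rows are anchors (minimum b, maximum
    tau_R, minimum tau_E, spanning b_delta and the frequency window); the
    remainder sample all axes pseudo-randomly: b log-uniform, b_delta from
    the preset's discrete set, centroid frequency uniform in the window,
    tau_R/tau_E log-uniform, orientations area-uniform on the sphere.
    """
    if preset not in PROTOCOL_PRESETS:
        raise ValueError(f"unknown protocol preset {preset!r}")
    if n_rows < 16:
        raise ValueError("n_rows must be >= 16")
    p = PROTOCOL_PRESETS[preset]
    rng = np.random.default_rng(seed)
    n_free = n_rows - N_ANCHOR_ROWS

    b = np.exp(rng.uniform(np.log(p["b"][0]), np.log(p["b"][1]), n_free))
    b_delta = rng.choice(p["b_delta"], size=n_free)
    omega = rng.uniform(p["omega_hz"][0], p["omega_hz"][1], n_free) * TWO_PI
    tau_r = np.exp(rng.uniform(np.log(p["tau_r"][0]), np.log(p["tau_r"][1]),
                               n_free))
    tau_e = np.exp(rng.uniform(np.log(p["tau_e"][0]), np.log(p["tau_e"][1]),
                               n_free))
    theta = np.arccos(rng.uniform(-1.0, 1.0, n_free))
    phi = rng.uniform(0.0, TWO_PI, n_free)

    na = N_ANCHOR_ROWS
    anchor_bd = np.resize(p["b_delta"], na)
    anchor_om = np.linspace(p["omega_hz"][0], p["omega_hz"][1], na) * TWO_PI
    b = np.concatenate([np.full(na, p["b"][0]), b])
    b_delta = np.concatenate([anchor_bd, b_delta])
    omega = np.concatenate([anchor_om, omega])
    tau_r = np.concatenate([np.full(na, p["tau_r"][1]), tau_r])
    tau_e = np.concatenate([np.full(na, p["tau_e"][0]), tau_e])
    theta = np.concatenate([np.zeros(na), theta])
    phi = np.concatenate([np.zeros(na), phi])
    return Protocol(b, b_delta, theta, phi, omega, tau_r, tau_e, name=preset)


# ------------------------------------------------------------------ tissues


@dataclass(frozen=True)
class TissuePreset:
    """Log-normal component generator for one tissue archetype.

    ``centers`` maps parameter name -> geometric center; ``spread`` is the
    common log-normal sigma (in log-space).  ``orientation`` is either
    ``"uniform"`` (area-uniform axes) or ``"fixed"`` (the preset axis plus
    a small jitter), the latter emulating coherent fiber bundles.
    """

    name: str
    centers: dict
    spread: float = 0.15
    n_components: int = 3
    orientation: str = "uniform"
    axis: tuple = (np.pi / 2.0, 0.0)   # (theta, phi) when orientation=fixed
    axis_jitter: float = 0.1

    def sample(self, rng: np.random.Generator, n: int | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
        """Draw (params (n, 9), weights (n,) summing to 1)."""
        n = self.n_components if n is None else n
        p = np.empty((n, 9))
        for key in ("D_par", "D_perp", "D0", "Gamma_par", "Gamma_perp",
                    "R1", "R2"):
            p[:, IDX[key]] = self.centers[key] * np.exp(
                rng.normal(0.0, self.spread, n))
        _enforce_d0(p)
        if self.orientation == "fixed":
            p[:, IDX["theta"]] = self.axis[0] + rng.normal(
                0.0, self.axis_jitter, n)
            p[:, IDX["phi"]] = self.axis[1] + rng.normal(
                0.0, self.axis_jitter, n)
        else:
            p[:, IDX["theta"]] = np.arccos(rng.uniform(0.0, 1.0, n))
            p[:, IDX["phi"]] = rng.uniform(0.0, TWO_PI, n)
        w = rng.dirichlet(np.full(n, 5.0))
        return p, w


TISSUE_PRESETS = {
    "wm_like": TissuePreset(
        "wm_like",
        centers=dict(D_par=0.60e-9, D_perp=0.08e-9, D0=0.65e-9,
                     Gamma_par=5e4, Gamma_perp=5e4, R1=1.2, R2=35.0),
        orientation="fixed"),
    "gm_like": TissuePreset(
        "gm_like",
        centers=dict(D_par=0.35e-9, D_perp=0.24e-9, D0=0.40e-9,
                     Gamma_par=5e4, Gamma_perp=5e4, R1=0.7, R2=18.0)),
    "fw_like": TissuePreset(
        "fw_like",
        centers=dict(D_par=2.0e-9, D_perp=2.0e-9, D0=2.1e-9,
                     Gamma_par=5e4, Gamma_perp=5e4, R1=0.35, R2=4.0),
        spread=0.08, n_components=2),
    "restricted_like": TissuePreset(
        "restricted_like",
        centers=dict(D_par=0.12e-9, D_perp=0.10e-9, D0=0.90e-9,
                     Gamma_par=300.0, Gamma_perp=300.0, R1=0.8, R2=25.0)),
}


@dataclass
class PhantomTruth:
    """Ground truth of a synthetic image: per-voxel tissue label and the
    exact component mixture generating its signal."""

    labels: np.ndarray           # (nx, ny, nz) array of tissue names
    components: dict             # (i, j, k) -> (params (m, 9), weights (m,))
    seed: int = 0

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "shape": list(self.shape),
            "labels": self.labels.astype(str).ravel(order="C").tolist(),
            "voxels": [
                {"index": list(ix), "params": p.tolist(),
                 "weights": w.tolist()}
                for ix, (p, w) in sorted(self.components.items())],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PhantomTruth":
        with open(path) as fh:
            payload = json.load(fh)
        shape = tuple(payload["shape"])
        labels = np.array(payload["labels"], dtype=object).reshape(shape,
                                                                   order="C")
        comps = {tuple(v["index"]): (np.array(v["params"]),
                                     np.array(v["weights"]))
                 for v in payload["voxels"]}
        return cls(labels=labels, components=comps, seed=payload["seed"])


def make_phantom(shape: tuple[int, int, int], layout: str = "stripes",
                 tissues: list[str] | None = None, seed: int = 0,
                 labelmap: np.ndarray | None = None) -> PhantomTruth:
    """Generate a labeled phantom with per-voxel ground-truth mixtures.

    Layouts: ``stripes`` (tissue bands along the first axis),
    ``nested_rings`` (concentric classes in-plane) or ``labelmap`` (caller
    supplies the class-name volume).
    """
    if tissues is None:
        tissues = ["wm_like", "gm_like", "fw_like"]
    unknown = set(tissues) - TISSUE_PRESETS.keys()
    if unknown:
        raise ValueError(f"unknown tissue preset(s): {sorted(unknown)}")
    nx, ny, nz = shape
    if min(shape) < 1:
        raise ValueError("shape must be positive")

    if layout == "stripes":
        stripe = np.array(tissues, dtype=object)[
            (np.arange(nx) * len(tissues)) // nx]
        labels = np.broadcast_to(stripe[:, None, None], shape).copy()
    elif layout == "nested_rings":
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        r = np.hypot(np.arange(nx)[:, None] - cx, np.arange(ny)[None] - cy)
        ring = np.minimum((r / (r.max() + 1e-9) * len(tissues)).astype(int),
                          len(tissues) - 1)
        labels = np.array(tissues, dtype=object)[ring][:, :, None]
        labels = np.broadcast_to(labels, shape).copy()
    elif layout == "labelmap":
        if labelmap is None:
            raise ValueError("layout='labelmap' requires labelmap")
        labels = np.asarray(labelmap, dtype=object)
        unknown = set(labels.ravel()) - TISSUE_PRESETS.keys()
        if unknown:
            raise ValueError(f"labelmap contains unknown class(es): "
                             f"{sorted(map(str, unknown))}")
    else:
        raise ValueError(f"unknown layout {layout!r}")

    rng = np.random.default_rng(seed)
    components = {}
    for ix in np.ndindex(shape):
        components[ix] = TISSUE_PRESETS[labels[ix]].sample(rng)
    return PhantomTruth(labels=labels, components=components, seed=seed)


def simulate_dataset(truth: PhantomTruth, protocol: Protocol,
                     snr: float = np.inf, seed: int = 0,
                     noise_kind: str = "rician") -> np.ndarray:
    """Forward-model signals of every phantom voxel under a protocol.

    Returns the noisy 4D volume (noise referenced to the volume's maximum
    noiseless signal); ``snr=inf`` gives the noiseless volume.
    """
    vol = np.zeros(truth.shape + (len(protocol),))
    for ix, (params, weights) in truth.components.items():
        vol[ix] = signal(params, weights, protocol)
    if np.isinf(snr):
        return vol
    return add_noise(vol, snr, kind=noise_kind, seed=seed,
                     s0_ref=float(vol.max()))
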