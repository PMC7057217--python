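"""Seeded synthetic diffraction datasets with Wilson statistics.

The generator enumerates Miller indices on an orthorhombic grid, draws true
normalized intensities from the Wilson distribution (unit exponential for
acentrics; squared standard normal for centrics), applies a resolution-
dependent expected intensity with optional anisotropic scaling and optional
translational-NCS modulation, and adds Gaussian measurement error.  Ground
truth (the true normalized intensity, the expected intensity, the tNCS
modulation factor) is carried alongside, so every downstream stage can be
tested without external data.

Conventions kept deliberately minimal: P1-style index enumeration over one
hemisphere, a user-assigned centric zone (default: the h0l plane, the plane
on which tNCS alternation is usually displayed) and epsilon = 1 outside
user-specified zones.  Full space-group machinery is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import NormalizedObservation

__all__ = ["SimulationConfig", "simulate", "simulate_shell"]

#: columns describing the simulated ground truth, dropped by the table writer
TRUTH_COLUMNS = ["Z_TRUE", "I_TRUE", "TNCS_FACTOR"]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Attributes
    ----------
    a, b, c : float
        Orthorhombic cell lengths in angstroms.
    d_min : float
        Resolution limit in angstroms.
    b_iso : float
        Overall isotropic B factor in A^2; the expected intensity falls off
        as ``exp(-b_iso * s2 / 2)`` with ``s2 = 1/d^2``.
    aniso_delta_b : tuple of float
        Diagonal anisotropic Delta-B components in A^2 (should be
        zero-trace); multiplies the expected intensity by
        ``exp(-(dB1*(h/a)^2 + dB2*(k/b)^2 + dB3*(l/c)^2) / 2)``.
    tncs_vector : tuple of float
        Fractional translation t of the tNCS proxy model.
    tncs_weight : float
        Interference weight w in [0, 1]; the expected intensity is modulated
        by ``(1 - w) + w * (1 + cos(2*pi*h.t))``, which averages to 1.
    noise_profile : {"constant", "linear"}
        Shape of sigma_I against resolution: constant, or growing linearly
        in s2 from ``noise_sigma/2`` at s2=0 to ``3*noise_sigma/2`` at the
        resolution limit (mean noise level preserved).
    noise_sigma : float or None
        sigma_I on the intensity scale.  None (default) picks the expected
        intensity at the resolution limit, which makes the outermost data
        weak (normalized sigma near 1) the way real data near their limit
        are.
    scale : float
        Overall intensity scale (the expected intensity at s2 = 0).
    centric_zone : str
        "h0l" (default) marks k = 0 reflections centric; "none" makes all
        reflections acentric.
    epsilon_zones : dict
        Optional mapping like {"00l": 2} assigning an epsilon factor to axial
        zones; everything else has epsilon 1.
    seed : int
        Seed for all stochastic draws; a fixed seed reproduces the dataset
        exactly.
    """

    a: float = 50.0
    b: float = 60.0
    c: float = 70.0
    d_min: float = 2.5
    b_iso: float = 30.0
    aniso_delta_b: tuple = (0.0, 0.0, 0.0)
    tncs_vector: tuple = (0.0, 0.0, 0.5)
    tncs_weight: float = 0.0
    noise_profile: str = "constant"
    noise_sigma: float | None = None
    scale: float = 100.0
    centric_zone: str = "h0l"
    epsilon_zones: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.d_min <= 0.0:
            raise ValueError("d_min must be positive")
        if min(self.a, self.b, self.c) <= 0.0:
            raise ValueError("cell lengths must be positive")
        if not (0.0 <= self.tncs_weight <= 1.0):
            raise ValueError("tncs_weight must lie in [0, 1]")
        if self.noise_profile not in ("constant", "linear"):
            raise ValueError(f"unknown noise profile {self.noise_profile!r}")
        if self.centric_zone not in ("h0l", "none"):
            raise ValueError(f"unknown centric zone rule {self.centric_zone!r}")


def _enumerate_hkl(cfg: SimulationConfig):
    """Unique reflections of one hemisphere to the resolution limit."""
    s_max = 1.0 / cfg.d_min
    h_max = int(math.floor(cfg.a * s_max))
    k_max = int(math.floor(cfg.b * s_max))
    l_max = int(math.floor(cfg.c * s_max))
    h, k, l = np.meshgrid(np.arange(-h_max, h_max + 1),
                          np.arange(-k_max, k_max + 1),
                          np.arange(0, l_max + 1), indexing="ij")
    h, k, l = h.ravel(), k.ravel(), l.ravel()
    # hemisphere: l > 0, or l = 0 and k > 0, or l = k = 0 and h > 0
    unique = (l > 0) | ((l == 0) & (k > 0)) | ((l == 0) & (k == 0) & (h > 0))
    s2 = (h / cfg.a) ** 2 + (k / cfg.b) ** 2 + (l / cfg.c) ** 2
    keep = unique & (s2 > 0.0) & (s2 <= s_max * s_max)
    return h[keep], k[keep], l[keep], s2[keep]


def simulate(config: SimulationConfig) -> pd.DataFrame:
    """Generate one reflection table with ground-truth columns.

    Returns a DataFrame with the canonical columns (H, K, L, D, CENTRIC,
    EPSILON, SIGMA_EXPECTED, IOBS, SIGIOBS) plus the truth columns Z_TRUE,
    I_TRUE and TNCS_FACTOR.
    """
    rng = np.random.default_rng(config.seed)
    h, k, l, s2 = _enumerate_hkl(config)
    n = h.size

    centric = np.zeros(n, dtype=bool)
    if config.centric_zone == "h0l":
        centric = k == 0

    epsilon = np.ones(n, dtype=int)
    for zone, eps in config.epsilon_zones.items():
        if zone == "00l":
            epsilon[(h == 0) & (k == 0)] = int(eps)
        elif zone == "0k0":
            epsilon[(h == 0) & (l == 0)] = int(eps)
        elif zone == "h00":
            epsilon[(k == 0) & (l == 0)] = int(eps)
        else:
            raise ValueError(f"unknown epsilon zone {zone!r}")

    db1, db2, db3 = config.aniso_delta_b
    aniso = np.exp(-0.5 * (db1 * (h / config.a) ** 2
                           + db2 * (k / config.b) ** 2
                           + db3 * (l / config.c) ** 2))
    tx, ty, tz = config.tncs_vector
    w = config.tncs_weight
    tncs = (1.0 - w) + w * (1.0 + np.cos(2.0 * np.pi * (h * tx + k * ty + l * tz)))
    sigma_big = config.scale * np.exp(-0.5 * config.b_iso * s2) * aniso * tncs

    z_true = np.where(centric,
                      rng.standard_normal(n) ** 2,
                      rng.exponential(size=n))
    i_true = epsilon * sigma_big * z_true

    s2_max = 1.0 / config.d_min**2
    base = config.noise_sigma
    if base is None:
        base = config.scale * math.exp(-0.5 * config.b_iso * s2_max)
    if config.noise_profile == "constant":
        sigma_i = np.full(n, base)
    else:
        sigma_i = base * (0.5 + s2 / s2_max)
    i_obs = i_true + rng.normal(0.0, sigma_i)

    return pd.DataFrame({
        "H": h, "K": k, "L": l,
        "D": 1.0 / np.sqrt(s2),
        "CENTRIC": centric.astype(int),
        "EPSILON": epsilon,
        "SIGMA_EXPECTED": sigma_big,
        "IOBS": i_obs,
        "SIGIOBS": sigma_i,
        "Z_TRUE": z_true,
        "I_TRUE": i_true,
        "TNCS_FACTOR": tncs,
    })


def simulate_shell(sigma_z: float, n: int, centric: bool = False,
                   seed: int = 0) -> list[NormalizedObservation]:
    """Draws from a resolution shell with constant normalized error.

    True normalized intensities come from the Wilson prior of the requested
    centricity; observations add Gaussian noise of standard deviation
    ``sigma_z``.  Used for expected-versus-actual information convergence
    checks.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if sigma_z <= 0.0:
        raise ValueError("sigma_z must be positive")
    rng = np.random.default_rng(seed)
    if centric:
        z = rng.standard_normal(n) ** 2
    else:
        z = rng.exponential(size=n)
    z_obs = z + rng.normal(0.0, sigma_z, size=n)
    return [NormalizedObservation(float(v), float(sigma_z), centric) for v in z_obs]
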