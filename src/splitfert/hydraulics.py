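"""van Genuchten-Mualem hydraulic closure for variably saturated soil.

Retention: Se(psi) = (1 + (alpha |psi|)^n)^(-m), m = 1 - 1/n, for psi < 0;
Se = 1 at or above saturation.  Conductivity (Mualem, pore-connectivity
l = 0.5): K = Ks Se^0.5 [1 - (1 - Se^(1/m))^m]^2.  Default parameters are
literature values for a silt loam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SoilHydraulics:
    theta_r: float = 0.067
    theta_s: float = 0.45
    alpha: float = 0.02  # 1/cm
    n_vg: float = 1.41
    Ks: float = 10.8  # cm/day

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_r < self.theta_s <= 1.0:
            raise ValueError("require 0 <= theta_r < theta_s <= 1")
        if self.alpha <= 0 or self.Ks <= 0:
            raise ValueError("alpha and Ks must be > 0")
        if self.n_vg <= 1.0:
            raise ValueError("van Genuchten n must be > 1")

    @property
    def m_vg(self) -> float:
        return 1.0 - 1.0 / self.n_vg

    def effective_saturation(self, psi: np.ndarray) -> np.ndarray:
        psi = np.asarray(psi, dtype=float)
        se = np.ones_like(psi)
        neg = psi < 0
        se[neg] = (1.0 + (self.alpha * np.abs(psi[neg])) ** self.n_vg) ** (-self.m_vg)
        return se

    def theta(self, psi: np.ndarray) -> np.ndarray:
        """Volumetric water content from pressure head (cm)."""
        return self.theta_r + (self.theta_s - self.theta_r) * self.effective_saturation(psi)

    def psi_from_theta(self, theta: np.ndarray) -> np.ndarray:
        """Inverse retention curve; theta clipped into (theta_r, theta_s)."""
        theta = np.asarray(theta, dtype=float)
        se = np.clip(
            (theta - self.theta_r) / (self.theta_s - self.theta_r), 1e-12, 1.0
        )
        psi = np.zeros_like(se)
        unsat = se < 1.0
        psi[unsat] = -(1.0 / self.alpha) * (
            se[unsat] ** (-1.0 / self.m_vg) - 1.0
        ) ** (1.0 / self.n_vg)
        return psi

    def conductivity(self, psi: np.ndarray) -> np.ndarray:
        """Unsaturated hydraulic conductivity K(psi), cm/day."""
        se = self.effective_saturation(psi)
        m = self.m_vg
        inner = 1.0 - (1.0 - se ** (1.0 / m)) ** m
        return self.Ks * np.sqrt(se) * inner**2

    def capacity(self, psi: np.ndarray) -> np.ndarray:
        """Specific moisture capacity C = d theta / d psi, 1/cm.

        Zero for psi >= 0; the solver adds a small storativity there to keep
        the saturated limit well posed.
        """
        psi = np.asarray(psi, dtype=float)
        c = np.zeros_like(psi)
        neg = psi < 0
        a, n, m = self.alpha, self.n_vg, self.m_vg
        ap = a * np.abs(psi[neg])
        c[neg] = (
            (self.theta_s - self.theta_r)
            * a
            * n
            * m
            * ap ** (n - 1.0)
            * (1.0 + ap**n) ** (-m - 1.0)
        )
        return c

    def theta_K_C(self, psi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fused evaluation of (theta, K, C) sharing one retention pass.

        Equivalent to calling theta, conductivity and capacity separately;
        used in the Picard loop where this is the dominant cost.
        """
        psi = np.asarray(psi, dtype=float)
        n, m, a = self.n_vg, self.m_vg, self.alpha
        dtheta = self.theta_s - self.theta_r
        neg = psi < 0
        ap = a * np.abs(psi[neg])
        apn = ap**n
        se = np.ones_like(psi)
        se[neg] = (1.0 + apn) ** (-m)
        theta = self.theta_r + dtheta * se
        inner = 1.0 - (1.0 - se ** (1.0 / m)) ** m
        K = self.Ks * np.sqrt(se) * inner**2
        C = np.zeros_like(psi)
        C[neg] = dtheta * a * n * m * ap ** (n - 1.0) * (1.0 + apn) ** (-m - 1.0)
        return theta, K, C

    def theta_at_flux(self, q: float) -> float:
        """Water content of the steady uniform-gravity-flux solution K(theta) = q.

        Solved by bisection on effective saturation; requires 0 < q <= Ks.
        """
        if not 0.0 < q <= self.Ks:
            raise ValueError("flux must be in (0, Ks]")
        lo, hi = 1e-9, 1.0
        m = self.m_vg
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            k = self.Ks * np.sqrt(mid) * (1.0 - (1.0 - mid ** (1.0 / m)) ** m) ** 2
            if k < q:
                lo = mid
            else:
                hi = mid
        se = 0.5 * (lo + hi)
        return self.theta_r + (self.theta_s - self.theta_r) * se
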