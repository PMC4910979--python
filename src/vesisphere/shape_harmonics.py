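"""Spherical-harmonic decomposition of vesicle shape.

Each frame's bead radii r(theta, phi) are fitted with a linear combination of
real orthonormal spherical harmonics of degree l = 0..3 (16 coefficients).
The model is linear in the coefficients, so the least-squares optimum is
found exactly by a linear solve; a generic numerical minimiser would converge
to the same point. The l=0 coefficient divided by sqrt(4*pi) is the mean
fitted radius ("radius-equivalent"), so its fluctuation across frames reads
directly as radius fluctuation; l=1 modes describe hemisphere shifts, l=2
flattening/elongation, l=3 more complex deformations.

Across a trajectory, per-mode standard deviations and autocorrelation
functions characterise which undulation modes are active and how slowly they
decorrelate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from .model_io import Trajectory, VesicleFrame
from .spherical_geometry import SphereFrameRef, weighted_center_and_radius

__all__ = [
    "MODES_LMAX3",
    "modes_up_to",
    "real_Ylm",
    "HarmonicFit",
    "CoefficientSeries",
    "fit_frame",
    "fit_trajectory",
    "series_stats",
]


def modes_up_to(lmax: int) -> list[tuple[int, int]]:
    """(l, m) mode list in the package's canonical order."""
    return [(l, m) for l in range(lmax + 1) for m in range(-l, l + 1)]


MODES_LMAX3 = modes_up_to(3)


def real_Ylm(l: int, m: int, theta, phi):
    """Real orthonormal spherical harmonic (Condon-Shortley-free convention).

    ``theta`` is the polar angle from +z, ``phi`` the azimuth. For m != 0 the
    real harmonics are sqrt(2) * (-1)^m times the real/imaginary part of the
    complex Y_l^m, which makes them orthonormal on the sphere and strips the
    Condon-Shortley sign.
    """
    if not 0 <= l:
        raise ValueError("l must be >= 0")
    if abs(m) > l:
        raise ValueError(f"|m| = {abs(m)} exceeds l = {l}")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if m == 0:
        out = np.real(sph_harm_y(l, 0, theta, phi))
    elif m > 0:
        out = np.sqrt(2.0) * (-1.0) ** m * np.real(sph_harm_y(l, m, theta, phi))
    else:
        out = np.sqrt(2.0) * (-1.0) ** m * np.imag(sph_harm_y(l, -m, theta, phi))
    return out if out.ndim else float(out)


@dataclass
class HarmonicFit:
    """Least-squares harmonic coefficients (nm) of one frame plus residual RMS."""

    coefficients: np.ndarray  # (n_modes,) nm, ordered as modes_up_to(lmax)
    residual_rms: float  # nm
    n_points_fit: int
    lmax: int = 3

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n_expected = (self.lmax + 1) ** 2
        if len(self.coefficients) != n_expected:
            raise ValueError(
                f"expected {n_expected} coefficients for lmax={self.lmax}, "
                f"got {len(self.coefficients)}"
            )
        if self.residual_rms < 0:
            raise ValueError("residual must be >= 0")

    @property
    def modes(self) -> list[tuple[int, int]]:
        return modes_up_to(self.lmax)

    def coefficient(self, l: int, m: int) -> float:
        return float(self.coefficients[self.modes.index((l, m))])

    @property
    def radius_equivalent(self) -> float:
        """Mean fitted radius: c(0,0) / sqrt(4*pi)."""
        return float(self.coefficients[0] / np.sqrt(4.0 * np.pi))

    def degree_power(self, l: int) -> float:
        """Rotation-invariant per-degree power sum_m c_lm^2."""
        idx = [i for i, (ll, _) in enumerate(self.modes) if ll == l]
        return float(np.sum(self.coefficients[idx] ** 2))


def _angles(positions: np.ndarray, ref: SphereFrameRef) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    v = positions - ref.center
    r = np.linalg.norm(v, axis=1)
    theta = np.arccos(np.clip(v[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    return r, theta, phi


def design_matrix(theta: np.ndarray, phi: np.ndarray, lmax: int = 3) -> np.ndarray:
    return np.column_stack([real_Ylm(l, m, theta, phi) for l, m in modes_up_to(lmax)])


def fit_frame(
    frame: VesicleFrame | np.ndarray,
    ref: SphereFrameRef | None = None,
    selection: np.ndarray | None = None,
    lmax: int = 3,
) -> HarmonicFit:
    """Fit radii r_i(theta_i, phi_i) with harmonics up to ``lmax``.

    ``frame`` may be a VesicleFrame (``selection`` defaults to all lipid
    beads) or a bare (n, 3) position array. ``ref`` provides the expansion
    centre; it is computed from the selection when omitted. The coefficients
    minimise sum_i (P_fit(theta_i, phi_i) - r_i)^2 exactly (linear least
    squares); the residual is the RMS misfit at the optimum.
    """
    if isinstance(frame, VesicleFrame):
        mask = frame.lipid_mask if selection is None else np.asarray(selection, dtype=bool)
        positions = frame.positions[mask]
    else:
        positions = np.asarray(frame, dtype=float)
        if selection is not None:
            positions = positions[np.asarray(selection, dtype=bool)]
    n_modes = (lmax + 1) ** 2
    if len(positions) < n_modes:
        raise ValueError(
            f"need at least {n_modes} beads to fit lmax={lmax}, got {len(positions)}"
        )
    if ref is None:
        ref = weighted_center_and_radius(positions)
    r, theta, phi = _angles(positions, ref)
    A = design_matrix(theta, phi, lmax)
    coeffs, _, rank, _ = np.linalg.lstsq(A, r, rcond=None)
    if rank < n_modes:
        raise np.linalg.LinAlgError(
            f"degenerate angular coverage: design matrix rank {rank} < {n_modes}"
        )
    residual = float(np.sqrt(np.mean((A @ coeffs - r) ** 2)))
    return HarmonicFit(
        coefficients=coeffs, residual_rms=residual, n_points_fit=len(positions), lmax=lmax
    )


def fit_trajectory(
    traj: Trajectory,
    selection: str | np.ndarray = "lipids",
    lmax: int = 3,
) -> list[HarmonicFit]:
    """Per-frame harmonic fits; the expansion centre is recomputed each frame.

    ``selection`` is ``"lipids"`` (all lipid beads, the default),
    ``"headgroup"`` (phosphate-layer beads only), or an explicit boolean mask.
    """
    fits = []
    for frame in traj:
        if isinstance(selection, str):
            if selection == "lipids":
                mask = frame.lipid_mask
            elif selection == "headgroup":
                mask = frame.headgroup_mask
            else:
                raise ValueError(f"unknown selection {selection!r}")
        else:
            mask = np.asarray(selection, dtype=bool)
        fits.append(fit_frame(frame, selection=mask, lmax=lmax))
    return fits


@dataclass
class CoefficientSeries:
    """Per-mode coefficient time series with SDs and autocorrelation.

    ``acf`` rows use the biased (1/n) estimator normalised by lag 0, which
    keeps the implied spectrum non-negative. Modes that are constant across
    frames have SD 0 and an undefined ACF, flagged by NaN rows and
    ``constant_modes``.
    """

    modes: list[tuple[int, int]]
    values: np.ndarray  # (n_frames, n_modes) nm
    sd: np.ndarray  # (n_modes,) nm
    acf: np.ndarray  # (n_modes, n_lags)
    lags: np.ndarray  # (n_lags,) in frames
    constant_modes: np.ndarray  # (n_modes,) bool

    def mode_index(self, l: int, m: int) -> int:
        return self.modes.index((l, m))

    def mode_sd(self, l: int, m: int) -> float:
        return float(self.sd[self.mode_index(l, m)])

    def acf_decay_time(self, l: int, m: int, threshold: float = 0.05) -> float:
        """Exponential decay time (in frames) of a mode's ACF.

        Fits ACF(k) ~ exp(-k/tau) by least squares on log ACF over the
        initial lags until the ACF first drops below ``threshold`` (or turns
        non-positive). NaN for constant modes or when no usable lags exist.
        """
        j = self.mode_index(l, m)
        if self.constant_modes[j]:
            return float("nan")
        a = self.acf[j]
        ks = []
        for k in range(1, len(a)):
            if not np.isfinite(a[k]) or a[k] <= threshold:
                break
            ks.append(k)
        if not ks:
            return float("nan")
        ks_arr = np.asarray(ks, dtype=float)
        logs = np.log(a[ks])
        # through-origin fit of log acf = -k/tau
        slope = float(np.sum(ks_arr * logs) / np.sum(ks_arr**2))
        if slope >= 0:
            return float("inf")
        return -1.0 / slope


def _acf_biased(x: np.ndarray, n_lags: int) -> np.ndarray:
    x = x - x.mean()
    n = len(x)
    c0 = np.dot(x, x) / n
    if c0 == 0:
        return np.full(n_lags, np.nan)
    full = np.correlate(x, x, mode="full")[n - 1 :] / n
    return full[:n_lags] / c0


def series_stats(fits: list[HarmonicFit], max_lag: int | None = None) -> CoefficientSeries:
    """SD and autocorrelation of each harmonic coefficient across frames."""
    if len(fits) < 2:
        raise ValueError("need at least 2 frames for coefficient statistics")
    lmax = fits[0].lmax
    values = np.stack([f.coefficients for f in fits])
    n_frames, n_modes = values.shape
    if max_lag is None:
        max_lag = min(n_frames // 2, 500)
    n_lags = max_lag + 1
    sd = values.std(axis=0, ddof=1)
    # constant up to float rounding: SD negligible against the mean level
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(values.mean(axis=0)))
    sd = np.where(constant, 0.0, sd)
    acf = np.empty((n_modes, n_lags))
    for j in range(n_modes):
        if constant[j]:
            acf[j] = np.nan
        else:
            acf[j] = _acf_biased(values[:, j], n_lags)
    return CoefficientSeries(
        modes=modes_up_to(lmax),
        values=values,
        sd=sd,
        acf=acf,
        lags=np.arange(n_lags),
        constant_modes=constant,
    )
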