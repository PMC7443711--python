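"""Monte Carlo photon transport on the voxel grid.

The engine is a voxel-stepping Monte Carlo with Henyey–Greenstein
scattering, continuous absorption weighting and a track-length fluence
estimator: along every straight segment of length ``l`` through a voxel a
photon of weight ``w`` deposits ``integral(w dl) = w (1 - exp(-mu_a l)) /
mu_a`` of path (exactly ``w l`` when ``mu_a = 0``), and the fluence is the
total deposited path per voxel volume per launched photon.  This steady
state estimator is equivalent to integrating the time-resolved flux over a
window long enough to capture all scattered photons: light crosses the
whole few-millimetre domain in tens of picoseconds, so the steady state is
reached essentially instantly on the acoustic time scale.

Photons exiting the domain are terminated (their weight tallied as
escaped); there is no internal refractive-index mismatch by default.  The
returned fluence carries no absolute energy unit — images are normalized
before entering the networks, so only relative amplitudes matter.

Randomness is a counter-based splitmix64 stream keyed on
``(seed, photon index)``: runs are bit-reproducible and independent of
execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from paovox.phantom import TissueModel

__all__ = [
    "BeamSpec",
    "FluenceVolume",
    "mc_fluence",
    "simulate_fluence",
    "initial_pressure",
    "fluence_correct",
]

_U64 = np.uint64
_MIX_GAMMA = _U64(0x9E3779B97F4A7C15)


@dataclass(frozen=True)
class BeamSpec:
    """Excitation beam on the z = 0 plane, propagating along +z.

    ``profile`` is ``gaussian`` (truncated at the domain edge), ``pencil``
    (single ray at the center) or ``uniform`` (flat over the whole plane).
    ``waist_mm`` defaults to 140 voxels scaled by (grid width / 120), the
    full-scale beam waist expressed in grid units.
    """

    profile: str = "gaussian"
    waist_mm: float | None = None
    center_mm: tuple[float, float] | None = None  # (y, x)

    def resolve(self, shape: tuple[int, int, int], dx_mm: float):
        nz, ny, nx = shape
        if self.waist_mm is None:
            waist = 140.0 * (nx / 120.0) * dx_mm
        else:
            waist = float(self.waist_mm)
        if waist <= 0:
            raise ValueError("beam waist must be positive")
        if self.center_mm is None:
            center = (0.5 * ny * dx_mm, 0.5 * nx * dx_mm)
        else:
            center = self.center_mm
        codes = {"gaussian": 0, "pencil": 1, "uniform": 2}
        if self.profile not in codes:
            raise ValueError(f"unknown beam profile {self.profile!r}")
        return codes[self.profile], waist, float(center[0]), float(center[1])


@dataclass
class FluenceVolume:
    """Per-voxel fluence estimate (normalized units) at one wavelength."""

    phi: np.ndarray
    lambda_nm: float
    n_photons: int
    seed: int
    absorbed: float
    escaped: float
    terminated: float

    @property
    def launched(self) -> float:
        return self.absorbed + self.escaped + self.terminated


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z + _MIX_GAMMA) & _U64(0xFFFFFFFFFFFFFFFF)
    s = z
    s = ((s ^ (s >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _U64(
        0xFFFFFFFFFFFFFFFF
    )
    s = ((s ^ (s >> _U64(27))) * _U64(0x94D049BB133111EB)) & _U64(
        0xFFFFFFFFFFFFFFFF
    )
    return s ^ (s >> _U64(31))


@njit(cache=True, inline="always")
def _rand(state):
    """Advance the splitmix64 state; return (state, uniform in (0, 1))."""
    state = (state + _MIX_GAMMA) & _U64(0xFFFFFFFFFFFFFFFF)
    s = state
    s = ((s ^ (s >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _U64(
        0xFFFFFFFFFFFFFFFF
    )
    s = ((s ^ (s >> _U64(27))) * _U64(0x94D049BB133111EB)) & _U64(
        0xFFFFFFFFFFFFFFFF
    )
    s = s ^ (s >> _U64(31))
    u = (s >> _U64(11)) * (1.0 / 9007199254740992.0)
    if u <= 0.0:
        u = 5e-324
    return state, u


@njit(cache=True)
def _mc_kernel(
    mu_a,
    mu_s,
    g_vol,
    dx,
    n_photons,
    seed,
    profile,
    waist,
    cy,
    cx,
    w_min,
    tally,
):
    nz, ny, nx = mu_a.shape
    depth = nz * dx
    height = ny * dx
    width = nx * dx
    absorbed = 0.0
    escaped = 0.0
    terminated = 0.0
    sigma = 0.5 * waist  # Gaussian intensity exp(-2 r^2 / w^2)
    eps = 1e-7 * dx

    for i in range(n_photons):
        state = _mix64(_U64(seed) ^ _mix64(_U64(i)))
        # --- launch position on the z = 0 plane
        if profile == 1:  # pencil
            py = cy
            px = cx
        elif profile == 2:  # uniform
            state, u1 = _rand(state)
            state, u2 = _rand(state)
            py = u1 * height
            px = u2 * width
        else:  # truncated Gaussian
            py = -1.0
            px = -1.0
            for _try in range(10000):
                state, u1 = _rand(state)
                state, u2 = _rand(state)
                r = sigma * math.sqrt(-2.0 * math.log(u1))
                phi_ang = 2.0 * math.pi * u2
                py = cy + r * math.cos(phi_ang)
                px = cx + r * math.sin(phi_ang)
                if 0.0 <= py < height and 0.0 <= px < width:
                    break
        pz = 0.0
        dz_, dy_, dx_ = 1.0, 0.0, 0.0
        w = 1.0
        state, u = _rand(state)
        tau = -math.log(u)  # dimensionless scattering depth

        while True:
            # explicit < 0 checks: int() truncates toward zero, so a voxel
            # index of 0 would otherwise alias positions just outside z = 0
            if (
                pz < 0.0
                or py < 0.0
                or px < 0.0
                or pz >= depth
                or py >= height
                or px >= width
            ):
                escaped += w
                break
            iz = int(pz / dx)
            iy = int(py / dx)
            ix = int(px / dx)
            if iz >= nz:
                iz = nz - 1
            if iy >= ny:
                iy = ny - 1
            if ix >= nx:
                ix = nx - 1
            ma = mu_a[iz, iy, ix]
            ms = mu_s[iz, iy, ix]

            # distance to the voxel boundary along the direction of flight
            d_bound = 1e30
            if dz_ > 0.0:
                d_bound = ((iz + 1) * dx - pz) / dz_
            elif dz_ < 0.0:
                d_bound = (iz * dx - pz) / dz_
            if dy_ > 0.0:
                t = ((iy + 1) * dx - py) / dy_
                if t < d_bound:
                    d_bound = t
            elif dy_ < 0.0:
                t = (iy * dx - py) / dy_
                if t < d_bound:
                    d_bound = t
            if dx_ > 0.0:
                t = ((ix + 1) * dx - px) / dx_
                if t < d_bound:
                    d_bound = t
            elif dx_ < 0.0:
                t = (ix * dx - px) / dx_
                if t < d_bound:
                    d_bound = t
            d_bound += eps  # overshoot so the next lookup lands in a new voxel

            scatter = False
            if ms > 0.0:
                d_scat = tau / ms
                if d_scat <= d_bound:
                    d = d_scat
                    scatter = True
                else:
                    d = d_bound
            else:
                d = d_bound

            # continuous absorption along the segment; track-length deposit
            if ma > 0.0:
                att = math.exp(-ma * d)
                tally[iz, iy, ix] += w * (1.0 - att) / ma
                absorbed += w * (1.0 - att)
                w *= att
            else:
                tally[iz, iy, ix] += w * d
            tau -= ms * d
            pz += dz_ * d
            py += dy_ * d
            px += dx_ * d

            if scatter:
                gg = g_vol[iz, iy, ix]
                state, u = _rand(state)
                if abs(gg) < 1e-6:
                    cost = 1.0 - 2.0 * u
                else:
                    tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * u)
                    cost = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                    if cost > 1.0:
                        cost = 1.0
                    elif cost < -1.0:
                        cost = -1.0
                sint = math.sqrt(1.0 - cost * cost)
                state, u = _rand(state)
                psi = 2.0 * math.pi * u
                cosp = math.cos(psi)
                sinp = math.sin(psi)
                if abs(dz_) > 0.99999:
                    nz_ = cost * (1.0 if dz_ > 0.0 else -1.0)
                    ny_ = sint * cosp
                    nx_ = sint * sinp
                else:
                    denom = math.sqrt(1.0 - dz_ * dz_)
                    nz_ = -sint * cosp * denom + dz_ * cost
                    ny_ = sint * (cosp * dz_ * dy_ - sinp * dx_) / denom + dy_ * cost
                    nx_ = sint * (cosp * dz_ * dx_ + sinp * dy_) / denom + dx_ * cost
                norm = math.sqrt(nz_ * nz_ + ny_ * ny_ + nx_ * nx_)
                dz_, dy_, dx_ = nz_ / norm, ny_ / norm, nx_ / norm
                state, u = _rand(state)
                tau = -math.log(u)

            if w < w_min:
                terminated += w
                break

    return absorbed, escaped, terminated


def mc_fluence(
    mu_a: np.ndarray,
    mu_s: np.ndarray,
    g: np.ndarray,
    dx_mm: float,
    n_photons: int,
    beam: BeamSpec | None = None,
    seed: int = 0,
    w_min: float = 1e-6,
) -> tuple[np.ndarray, float, float, float]:
    """Run the Monte Carlo on raw coefficient volumes (mm^-1).

    Returns ``(phi, absorbed, escaped, terminated)`` where ``phi`` is the
    fluence per launched photon per voxel volume and the three scalars are
    weight tallies (their sum equals the launched weight ``n_photons``).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if not (mu_a.shape == mu_s.shape == g.shape):
        raise ValueError("coefficient volumes must share one shape")
    if beam is None:
        beam = BeamSpec()
    profile, waist, cy, cx = beam.resolve(mu_a.shape, dx_mm)
    tally = np.zeros(mu_a.shape, dtype=np.float64)
    absorbed, escaped, terminated = _mc_kernel(
        np.ascontiguousarray(mu_a, dtype=np.float64),
        np.ascontiguousarray(mu_s, dtype=np.float64),
        np.ascontiguousarray(g, dtype=np.float64),
        float(dx_mm),
        int(n_photons),
        np.uint64(seed),
        profile,
        waist,
        cy,
        cx,
        float(w_min),
        tally,
    )
    phi = tally / (n_photons * dx_mm**3)
    return phi, absorbed, escaped, terminated


def simulate_fluence(
    model: TissueModel,
    lambda_nm: float,
    n_photons: int,
    beam: BeamSpec | None = None,
    seed: int = 0,
    w_min: float = 1e-6,
) -> FluenceVolume:
    """Simulate the fluence of one phantom at one excitation wavelength."""
    lam = float(lambda_nm)
    if lam not in model.mu_a:
        raise KeyError(f"model has no optical properties at {lam} nm")
    phi, absorbed, escaped, terminated = mc_fluence(
        model.mu_a[lam],
        model.mu_s[lam],
        model.g,
        model.grid.dx_mm,
        n_photons,
        beam=beam,
        seed=seed,
        w_min=w_min,
    )
    return FluenceVolume(
        phi=phi,
        lambda_nm=lam,
        n_photons=int(n_photons),
        seed=int(seed),
        absorbed=absorbed,
        escaped=escaped,
        terminated=terminated,
    )


def initial_pressure(
    model: TissueModel, phi: FluenceVolume | np.ndarray, lambda_nm: float
) -> np.ndarray:
    """Initial pressure p0 = mu_a(lambda) * Gamma * Phi, voxelwise."""
    phi_arr = phi.phi if isinstance(phi, FluenceVolume) else np.asarray(phi)
    lam = float(lambda_nm)
    mu_a = model.mu_a[lam]
    if phi_arr.shape != mu_a.shape:
        raise ValueError("fluence shape does not match the model grid")
    return mu_a * model.gamma * phi_arr


def fluence_correct(
    image: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise fluence division: recover relative mu_a * Gamma.

    Voxels where the fluence vanishes are masked to 0 and flagged in the
    returned boolean volume rather than producing a division error.
    """
    image = np.asarray(image, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if image.shape != phi.shape:
        raise ValueError("image and fluence shapes differ")
    flagged = phi == 0
    out = np.zeros_like(image)
    np.divide(image, phi, out=out, where=~flagged)
    return out, flagged
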