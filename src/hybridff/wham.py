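"""Weighted histogram analysis (WHAM) and PMF minimum descriptors.

Umbrella windows biased at a ladder of centres along the pair COM
separation are combined into one unbiased potential of mean force by the
standard self-consistent WHAM iteration:

    p(b)  = sum_w H_w(b) / sum_w N_w exp(beta*(f_w - w_w(b)))
    f_w   = -kT ln sum_b exp(-beta w_w(b)) p(b)

iterated until the window free-energy offsets f_w stop moving.  The PMF
is F(b) = -kT ln p(b), reported under an explicit zero convention.  The
first-minimum descriptors (depth relative to the large-r plateau, and
position) are the quantities the pair-parameter fit matches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sampler import UmbrellaWindow
from .units import kt

ZERO_CONVENTIONS = ("zero-at-rmax", "min-is-zero")


class WhamConvergenceError(RuntimeError):
    """WHAM could not converge (window gap or iteration limit)."""


class NoMinimumError(ValueError):
    """A profile needed for a comparison has no interior minimum."""


@dataclass
class PMFProfile:
    """Free energy versus pair separation on a fixed grid.

    ``r`` holds strictly increasing bin centres (nm); ``f`` the free
    energy (kJ/mol, NaN where unsampled); ``counts`` per-bin totals.
    """

    r: np.ndarray
    f: np.ndarray
    temperature: float = 310.0
    zero: str = "zero-at-rmax"
    counts: np.ndarray | None = None

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("separation grid must be strictly increasing")
        if self.zero not in ZERO_CONVENTIONS:
            raise ValueError(f"unknown zero convention {self.zero!r}")
        if self.counts is None:
            self.counts = np.full(len(self.r), np.inf)
        else:
            self.counts = np.asarray(self.counts, dtype=float)
        populated = self.counts > 0
        if not np.all(np.isfinite(self.f[populated])):
            raise ValueError("free energy must be finite on populated bins")

    @property
    def populated(self) -> np.ndarray:
        return (self.counts > 0) & np.isfinite(self.f)

    def normalized(self) -> "PMFProfile":
        """Copy with the zero convention applied to the values."""
        f = self.f.copy()
        pop = self.populated
        if self.zero == "zero-at-rmax":
            f -= f[np.flatnonzero(pop)[-1]]
        else:
            f -= np.nanmin(f[pop])
        return PMFProfile(self.r, f, self.temperature, self.zero, self.counts)


@dataclass
class MinimumDescriptor:
    """First-minimum depth (positive magnitude, kJ/mol) and position (nm)."""

    depth: float
    position: float

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth is a positive magnitude")


def pmf_from_potential(u, grid, temperature=310.0, zero="zero-at-rmax") -> PMFProfile:
    """Exact PMF of an isolated pair: the potential itself on a grid.

    For a scalar pair coordinate without Jacobian correction the PMF
    equals the pair potential up to an additive constant; this is the
    analytic oracle used by fits and tests.
    """
    grid = np.asarray(grid, dtype=float)
    prof = PMFProfile(grid, np.asarray(u(grid), dtype=float), temperature, zero)
    return prof.normalized()


def _histogram(windows, edges):
    counts = np.stack([np.histogram(w.production, bins=edges)[0] for w in windows])
    return counts.astype(float)


def wham(
    windows: list[UmbrellaWindow],
    grid=(0.25, 1.0, 0.01),
    temperature: float = 310.0,
    tol: float = 1e-7,
    max_iter: int = 100000,
    zero: str = "zero-at-rmax",
    jacobian: bool = False,
) -> PMFProfile:
    """Reconstruct a PMF from umbrella windows by self-consistent WHAM.

    ``grid`` is (r_min, r_max, bin_width).  Iteration stops when the
    maximum change in the window offsets f_w drops below ``tol`` (kJ/mol).
    Adjacent windows (ordered by centre) must share at least one
    populated bin; a gap raises :class:`WhamConvergenceError` naming its
    location.  With ``jacobian=True`` the radial entropy 2kT ln r is
    removed from the profile (off by default).
    """
    if len(windows) == 0:
        raise ValueError("need at least one window")
    r_min, r_max, width = grid
    edges = np.arange(r_min, r_max + 0.5 * width, width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    order = np.argsort([w.center for w in windows])
    windows = [windows[i] for i in order]
    hist = _histogram(windows, edges)
    n_w = hist.sum(axis=1)
    if np.any(n_w == 0):
        idx = int(np.flatnonzero(n_w == 0)[0])
        raise WhamConvergenceError(
            f"window centred at {windows[idx].center:.3f} nm has no samples on the grid"
        )
    for a in range(len(windows) - 1):
        shared = (hist[a] > 0) & (hist[a + 1] > 0)
        if not shared.any():
            raise WhamConvergenceError(
                "non-overlapping window chain: no shared bins between windows centred at "
                f"{windows[a].center:.3f} and {windows[a + 1].center:.3f} nm"
            )
        if hist[a][shared].sum() < 10:
            warnings.warn(
                f"weak histogram overlap near {windows[a].center:.3f} nm", stacklevel=2
            )

    kT = kt(temperature)
    beta = 1.0 / kT
    bias = np.stack([w.bias_energy(centers) for w in windows])  # (W, B)
    log_c = -beta * bias
    h_tot = hist.sum(axis=0)
    f_w = np.zeros(len(windows))
    populated = h_tot > 0
    from scipy.special import logsumexp

    log_hist_tot = np.where(populated, np.log(np.where(populated, h_tot, 1.0)), -np.inf)
    log_n = np.log(n_w)
    residual = np.inf
    for _ in range(max_iter):
        # log denominator per bin: logsumexp over windows
        log_den = logsumexp(log_n[:, None] + beta * f_w[:, None] + log_c, axis=0)
        log_p = log_hist_tot - log_den
        f_new = -kT * logsumexp(log_c + log_p[None, :], axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f_w)))
        f_w = f_new
        if residual < tol:
            break
    else:
        raise WhamConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (last residual {residual:.3e} kJ/mol)"
        )
    f = np.where(populated, -kT * log_p, np.nan)
    if jacobian:
        f = f - 2.0 * kT * np.log(centers)
    prof = PMFProfile(centers, f, temperature, zero, counts=h_tot)
    return prof.normalized()


# ---------------------------------------------------------------------------
# minimum descriptors
# ---------------------------------------------------------------------------

def _moving_average(y, width):
    if width <= 1:
        return y
    kernel = np.ones(width) / width
    pad = width // 2
    ypad = np.pad(y, pad, mode="edge")
    out = np.convolve(ypad, kernel, mode="same")[pad:pad + len(y)]
    return out


def first_minimum(pmf: PMFProfile, smoothing: int = 0, plateau_bins: int = 1) -> MinimumDescriptor | None:
    """First local minimum of a profile, scanning from small r.

    Depth is measured relative to the large-r plateau, as a positive
    magnitude; position is refined to sub-bin accuracy by a parabola
    through the minimum bin and its neighbours.  Returns ``None`` (a
    no-minimum result, not an error) for profiles without an interior
    minimum.  ``smoothing`` is a moving-average width in bins.
    ``plateau_bins`` sets how many trailing populated bins estimate the
    plateau (median): 1 anchors at the last bin (exact for analytic
    profiles); larger values suppress single-bin noise on sampled
    profiles.
    """
    pop = pmf.populated
    idx = np.flatnonzero(pop)
    if len(idx) < 5:
        raise ValueError("profile needs at least 5 populated bins")
    r = pmf.r[idx]
    f = pmf.f[idx]
    fs = _moving_average(f, smoothing) if smoothing and smoothing > 1 else f
    k = int(max(1, min(plateau_bins, len(f) - 1)))
    ref = float(np.median(f[-k:]))  # large-r plateau
    for i in range(1, len(fs) - 1):
        if fs[i] < fs[i - 1] and fs[i] <= fs[i + 1]:
            # parabolic refinement on the unsmoothed values
            x0, x1, x2 = r[i - 1], r[i], r[i + 1]
            y0, y1, y2 = f[i - 1], f[i], f[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom > 0:
                # parabola vertex on a uniform 3-point stencil
                shift = 0.5 * (y0 - y2) / denom  # in units of bin width
                pos = x1 + shift * (x2 - x0) / 2.0
                fmin = y1 - 0.125 * (y0 - y2) ** 2 / denom
            else:
                pos, fmin = x1, y1
            depth = max(0.0, ref - fmin)
            return MinimumDescriptor(depth=depth, position=float(pos))
    return None


def pmf_deviation(model: PMFProfile, reference: PMFProfile, smoothing: int = 0, plateau_bins: int = 1):
    """(|delta depth|, |delta position|) of the two first minima.

    These are the per-pair descriptors whose averages summarise fit
    quality across an analog suite.  Raises :class:`NoMinimumError`
    naming the profile that lacks a minimum.
    """
    descriptors = []
    for name, prof in (("model", model), ("reference", reference)):
        d = first_minimum(prof, smoothing=smoothing, plateau_bins=plateau_bins)
        if d is None:
            raise NoMinimumError(f"{name} profile has no first minimum")
        descriptors.append(d)
    a, b = descriptors
    return abs(a.depth - b.depth), abs(a.position - b.position)


# ---------------------------------------------------------------------------
# columnar I/O (dialect: r_nm F_kJmol counts)
# ---------------------------------------------------------------------------

def write_pmf(pmf: PMFProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# temperature_K={pmf.temperature} zero={pmf.zero}\n")
        fh.write("# r_nm F_kJmol counts\n")
        for r, f, c in zip(pmf.r, pmf.f, pmf.counts):
            c_out = -1.0 if np.isinf(c) else c
            fh.write(f"{r:.6f} {f:.8f} {c_out:.1f}\n")


def read_pmf(path) -> PMFProfile:
    temperature, zero = 310.0, "zero-at-rmax"
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("temperature_K="):
                        temperature = float(tok.split("=", 1)[1])
                    elif tok.startswith("zero="):
                        zero = tok.split("=", 1)[1]
                continue
            if line:
                rows.append([float(x) for x in line.split()])
    arr = np.asarray(rows)
    counts = np.where(arr[:, 2] < 0, np.inf, arr[:, 2])
    return PMFProfile(arr[:, 0], arr[:, 1], temperature, zero, counts)
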