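"""Elution profile cleaning and Gaussian deconvolution.

A co-fractionation experiment measures each protein's abundance across ordered
size-exclusion chromatography (SEC) fractions; the resulting per-protein trace
(its "chromatogram") is the raw evidence for co-complex membership.  Before
pairs of proteins are scored for co-elution, each profile is cleaned (isolated
missing values imputed, unsupported short runs of observations removed) and
deconvolved into a small number of Gaussian peaks, whose centers are later used
for co-apex features.

Fraction coordinates are 1-based throughout: fraction 1 is the earliest-eluting
(largest apparent size) fraction.  Missing measurements are encoded as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .errors import ProfileFitError

__all__ = [
    "ElutionProfile",
    "GaussianComponent",
    "CoFractionationDataset",
    "clean_profile",
    "fit_gaussians",
]

#: Minimum Gaussian peak width (in fractions) allowed during fitting; narrower
#: components tend to chase single noisy fractions.  Also bounds how far outside
#: the fraction axis a truncated peak may center.
MIN_WIDTH = 0.8


@dataclass
class ElutionProfile:
    """One protein's abundance across ordered SEC fractions in one condition.

    Parameters
    ----------
    protein_id:
        Protein (group) identifier.
    condition:
        Experimental condition label, e.g. ``"inhibited"``.
    values:
        Float array of length ``n_fractions``; NaN marks a missing measurement.
        Observed values must be non-negative.
    """

    protein_id: str
    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and (observed < 0).any():
            raise ValueError(
                f"profile {self.protein_id!r} contains negative abundances"
            )

    @property
    def n_fractions(self) -> int:
        return self.values.size

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())


@dataclass(frozen=True)
class GaussianComponent:
    """A single Gaussian elution peak: ``amplitude * exp(-(x-center)^2 / 2 width^2)``."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if not self.width > 0:
            raise ValueError("width must be positive")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((x - self.center) / self.width) ** 2)


@dataclass
class CoFractionationDataset:
    """A per-condition protein-by-fraction matrix, stored as keyed profiles."""

    condition: str
    profiles: dict[str, ElutionProfile] = field(default_factory=dict)
    n_fractions: int = 0

    def __post_init__(self) -> None:
        for pid, prof in self.profiles.items():
            if prof.n_fractions != self.n_fractions:
                raise ValueError(
                    f"profile {pid!r} has {prof.n_fractions} fractions, "
                    f"expected {self.n_fractions}"
                )

    @property
    def protein_ids(self) -> list[str]:
        return sorted(self.profiles)

    def to_matrix(self) -> np.ndarray:
        """Return an (n_proteins, n_fractions) float matrix in protein-id order."""
        return np.array([self.profiles[p].values for p in self.protein_ids])


def clean_profile(profile: ElutionProfile, min_consecutive: int = 5) -> ElutionProfile:
    """Impute isolated gaps and drop short observation runs.

    A single missing fraction flanked by two observed fractions is imputed as
    the mean of its neighbors (imputation is simultaneous, based on the input's
    observation mask).  Afterwards, any maximal run of observed fractions
    shorter than ``min_consecutive`` is set to missing: isolated identifications
    carry no co-elution information and are treated as noise.  The operation is
    idempotent and never changes the profile length.
    """
    v = profile.values.copy()
    obs = ~np.isnan(v)
    n = v.size
    if n >= 3:
        single = ~obs[1:-1] & obs[:-2] & obs[2:]
        idx = np.where(single)[0] + 1
        v[idx] = 0.5 * (v[idx - 1] + v[idx + 1])
    obs = ~np.isnan(v)
    # remove observed runs shorter than min_consecutive
    i = 0
    while i < n:
        if obs[i]:
            j = i
            while j < n and obs[j]:
                j += 1
            if j - i < min_consecutive:
                v[i:j] = np.nan
            i = j
        else:
            i += 1
    return replace(profile, values=v)


def _model(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Sum-of-Gaussians model; params is a flat [amp, center, width] * k vector."""
    y = np.zeros_like(x, dtype=float)
    for a, c, w in params.reshape(-1, 3):
        y += a * np.exp(-0.5 * ((x - c) / w) ** 2)
    return y


def _rss(x: np.ndarray, y: np.ndarray, params: np.ndarray) -> float:
    r = _model(x, params) - y
    return float(r @ r)


def _candidate_centers(values: np.ndarray) -> list[int]:
    """Local maxima of the smoothed, zero-filled profile, tallest first (1-based)."""
    filled = np.where(np.isnan(values), 0.0, values)
    smoothed = gaussian_filter1d(filled, sigma=1.5)
    peaks, _ = find_peaks(smoothed)
    order = peaks[np.argsort(smoothed[peaks])[::-1]]
    centers = [int(p) + 1 for p in order]
    if not centers:
        centers = [int(np.argmax(filled)) + 1]
    return centers


def fit_path(
    profile: ElutionProfile,
    max_components: int = 5,
    min_points: int = 5,
) -> dict[int, tuple[np.ndarray, float]]:
    """Best sum-of-Gaussians fit for each component count 1..max_components.

    Returns a map ``k -> (flat parameter vector, residual sum of squares)``.
    The raw best-fit residual is non-increasing in ``k``: each ``k``-component
    search is seeded with the (k-1)-component solution plus a vanishing extra
    component, so adding a component can never be worse than not using it.
    Deterministic: all starts are derived from the data, no random restarts.
    """
    mask = profile.observed_mask
    if int(mask.sum()) < min_points:
        raise ProfileFitError(
            f"profile {profile.protein_id!r} has {int(mask.sum())} observed "
            f"fractions; at least {min_points} are required for fitting"
        )
    n = profile.n_fractions
    x = np.arange(1, n + 1, dtype=float)[mask]
    y = profile.values[mask]
    n_obs = x.size
    ymax = float(y.max()) if y.max() > 0 else 1.0

    lo = np.array([1e-9, 1.0 - 2 * MIN_WIDTH, MIN_WIDTH])
    hi = np.array([10.0 * ymax, n + 2 * MIN_WIDTH, max(n / 2.0, 2 * MIN_WIDTH)])
    centers = _candidate_centers(profile.values)

    results: dict[int, tuple[np.ndarray, float]] = {}
    prev: np.ndarray | None = None
    for k in range(1, max_components + 1):
        if 3 * k > n_obs:
            break
        inits: list[np.ndarray] = []
        if len(centers) >= k:
            p0 = []
            for c in centers[:k]:
                amp = max(float(profile.values[c - 1]) if mask[c - 1] else ymax, 1e-6)
                p0.extend([amp, float(c), 2.0])
            inits.append(np.array(p0))
        guard: np.ndarray | None = None
        if prev is not None:
            resid = y - _model(x, prev)
            i = int(np.argmax(np.abs(resid)))
            amp = max(float(resid[i]), 1e-6)
            inits.append(np.concatenate([prev, [amp, float(x[i]), 1.5]]))
            # vanishing extra component: reproduces the (k-1)-fit residual
            guard = np.concatenate([prev, [1e-9, float(x[i]), 1.0]])
        if not inits:
            inits.append(np.tile([ymax, float(np.mean(x)), 2.0], k))

        best_params, best_rss = None, np.inf
        for p0 in inits:
            p0c = np.clip(p0, np.tile(lo, k), np.tile(hi, k))
            try:
                sol = least_squares(
                    lambda p: _model(x, p) - y,
                    p0c,
                    bounds=(np.tile(lo, k), np.tile(hi, k)),
                    max_nfev=300 * k,
                )
            except Exception:  # singular start; fall through to other inits
                continue
            rss = float(sol.fun @ sol.fun)
            if rss < best_rss:
                best_params, best_rss = sol.x, rss
        if guard is not None:
            grss = _rss(x, y, guard)
            if best_params is None or grss < best_rss:
                best_params, best_rss = guard, grss
        if best_params is None:
            break
        results[k] = (best_params, best_rss)
        prev = best_params
    if not results:
        raise ProfileFitError(
            f"profile {profile.protein_id!r}: no Gaussian fit converged"
        )
    return results


def fit_gaussians(
    profile: ElutionProfile,
    max_components: int = 5,
    min_points: int = 5,
) -> list[GaussianComponent]:
    """Deconvolve a profile into 1..max_components Gaussian peaks.

    The component count is chosen by AIC over penalized squared error
    (``n ln(RSS/n) + 2 * 3k``); fits are least-squares on observed fractions
    only (missing values are excluded, never zero-filled).  Peak centers may
    fall slightly outside the fraction axis (within two minimal widths) to
    accommodate peaks truncated at the column boundaries.

    Raises
    ------
    ProfileFitError
        If fewer than ``min_points`` fractions are observed.
    """
    results = fit_path(profile, max_components=max_components, min_points=min_points)
    n_obs = profile.n_observed
    best_k, best_aic = None, np.inf
    for k, (_, rss) in results.items():
        aic = n_obs * np.log(rss / n_obs + 1e-12) + 2.0 * 3 * k
        if aic < best_aic - 1e-9:
            best_k, best_aic = k, aic
    params = results[best_k][0].reshape(-1, 3)
    comps = [
        GaussianComponent(amplitude=float(a), center=float(c), width=float(w))
        for a, c, w in params
        if a > 1e-8  # drop the vanishing guard component if it survived selection
    ]
    if not comps:  # pathological: keep the largest component regardless
        a, c, w = max(params.tolist(), key=lambda p: p[0])
        comps = [GaussianComponent(float(a), float(c), float(w))]
    return sorted(comps, key=lambda g: g.center)
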