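"""Ordered-subsets expectation maximization (OS-EM) reconstruction.

OS-EM is maximum-likelihood fitting of a Poisson emission model to projection
data, accelerated by updating with angular subsets; with one subset it reduces
to ML-EM.  The module follows a model/results pattern: :class:`OSEMModel`
binds the data (a projection set, an attenuation map, the system model and an
additive scatter estimate) and :meth:`OSEMModel.fit` runs the multiplicative
updates for a :class:`ReconScheme`, returning :class:`OSEMResults` with one
image snapshot per completed iteration and an optional log-likelihood trace.

Reconstruction schemes obey two constraints throughout: the number of subsets
is an even integer divisor of the number of projections with at least two
angles per subset, and the product of iterations and projections does not
exceed 2400 (a proxy for a fixed reconstruction-time budget).

Measured counts are divided by the time per projection before reconstruction,
so reconstructed voxel values are in count-rate concentration units; a
calibration factor (see :mod:`spectpareto.calibration`) converts them to
MBq/mL.  This normalization leaves the EM updates unchanged — numerator and
denominator scale identically — so the iterates equal those of a
count-domain reconstruction divided by time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import ProjectionSet
from .phantoms import AttenuationMap, Grid
from .projector import Projector
from .system import SystemModel

__all__ = [
    "ReconScheme",
    "MAX_ITER_PROJ_PRODUCT",
    "enumerate_recon_schemes",
    "make_subsets",
    "poisson_loglik",
    "OSEMModel",
    "OSEMResults",
    "osem_reconstruct",
]

#: Cap on num_iterations * num_projections (reconstruction-time budget proxy).
MAX_ITER_PROJ_PRODUCT = 2400


@dataclass(frozen=True)
class ReconScheme:
    """A (projections, subsets, iterations) reconstruction setting."""

    num_projections: int
    num_subsets: int
    num_iterations: int

    def __post_init__(self) -> None:
        n, s, it = self.num_projections, self.num_subsets, self.num_iterations
        # s == 1 is plain ML-EM (allowed as a special case); otherwise the
        # study rule applies: even divisor with >= 2 angles per subset.
        if s != 1:
            if s < 2 or s % 2 != 0:
                raise ValueError(f"number of subsets must be even and >= 2, got {s}")
            if n % s != 0:
                raise ValueError(f"{s} subsets do not evenly divide {n} projections")
            if n // s < 2:
                raise ValueError(
                    f"need at least two projections per subset ({n} projections, {s} subsets)"
                )
        if it < 1:
            raise ValueError("need at least one iteration")
        if it * n > MAX_ITER_PROJ_PRODUCT:
            raise ValueError(
                f"iterations x projections = {it * n} exceeds {MAX_ITER_PROJ_PRODUCT}"
            )

    @property
    def updates(self) -> int:
        return self.num_subsets * self.num_iterations


def enumerate_recon_schemes(
    num_projections: int, max_product: int = MAX_ITER_PROJ_PRODUCT
) -> list[ReconScheme]:
    """All schemes for a projection count under the subset and budget rules.

    Subsets are the even integer divisors of ``num_projections`` leaving at
    least two angles per subset; iteration counts run from 1 up to
    ``max_product // num_projections``.
    """
    n = num_projections
    subsets = [d for d in range(2, n // 2 + 1, 2) if n % d == 0]
    max_iter = max_product // n
    return [
        ReconScheme(n, s, it) for s in subsets for it in range(1, max_iter + 1)
    ]


def make_subsets(angle_indices, num_subsets: int) -> list[np.ndarray]:
    """Interleaved angular subsets: subset i holds angles {i, i+S, i+2S, ...}.

    Processing order is the natural order 0..S-1.
    """
    angle_indices = np.asarray(angle_indices)
    n = angle_indices.size
    s = num_subsets
    if s != 1 and (s < 2 or s % 2 != 0 or n % s != 0 or n // s < 2):
        raise ValueError(
            f"{s} subsets invalid for {n} angles (even divisor with >= 2 angles "
            "per subset required)"
        )
    return [angle_indices[i::s] for i in range(s)]


def poisson_loglik(counts: np.ndarray, expected: np.ndarray) -> float:
    """Poisson log-likelihood sum(p log lambda - lambda), constants dropped.

    Returns -inf if any expected value is zero where counts are positive.
    """
    p = np.asarray(counts, dtype=float)
    lam = np.asarray(expected, dtype=float)
    if np.any((lam <= 0) & (p > 0)):
        return -np.inf
    pos = p > 0
    return float(np.sum(p[pos] * np.log(lam[pos])) - lam.sum())


class OSEMResults:
    """Per-iteration reconstructed volumes and fit diagnostics.

    Volumes are in count-rate concentration units (before calibration);
    ``iterates[k]`` is the image after k+1 full iterations.
    """

    def __init__(self, model: "OSEMModel", scheme: ReconScheme, iterates, loglik=None):
        self.model = model
        self.scheme = scheme
        self.iterates = iterates
        self.loglik = loglik

    @property
    def image(self) -> np.ndarray:
        return self.iterates[-1]

    def iterate(self, num_iterations: int) -> np.ndarray:
        """Image after ``num_iterations`` full iterations (1-based)."""
        if not 1 <= num_iterations <= len(self.iterates):
            raise ValueError(
                f"iteration {num_iterations} not in 1..{len(self.iterates)}"
            )
        return self.iterates[num_iterations - 1]

    def voi_mean(self, mask: np.ndarray, num_iterations: int | None = None) -> float:
        img = self.image if num_iterations is None else self.iterate(num_iterations)
        return float(img[mask].mean())

    def summary(self) -> str:
        s = self.scheme
        lines = [
            "OS-EM reconstruction results",
            "-" * 34,
            f"projections:      {s.num_projections}",
            f"subsets:          {s.num_subsets}",
            f"iterations:       {s.num_iterations}",
            f"updates:          {s.updates}",
            f"grid:             {self.model.grid.shape} @ {self.model.grid.voxel_size} mm",
            f"image total:      {self.image.sum() * self.model.grid.voxel_volume_mL:.6g} (rate-conc. x mL)",
        ]
        if self.loglik is not None:
            lines.append(f"final log-lik.:   {self.loglik[-1]:.6g}")
        return "\n".join(lines)


class OSEMModel:
    """Poisson emission model bound to one projection data set.

    Parameters
    ----------
    projections
        Measured (or simulated) counts with acquisition metadata.
    attenuation
        Attenuation map for the compensation; may be None (no attenuation).
    system
        Camera model used for the projector (resolution compensation).
    scatter_rate
        Additive scatter estimate in counts/s per pixel, aligned with the
        projection angles; defaults to zero (no scatter compensation).
    projector
        Optional pre-built :class:`Projector` to share rotation/attenuation
        caches across fits on the same geometry.
    """

    def __init__(
        self,
        projections: ProjectionSet,
        attenuation: AttenuationMap | None,
        system: SystemModel,
        scatter_rate: np.ndarray | None = None,
        grid: Grid | None = None,
        projector: Projector | None = None,
    ):
        if attenuation is None and grid is None and projector is None:
            raise ValueError("need an attenuation map, a grid, or a projector")
        self.projections = projections
        self.system = system
        if projector is not None:
            self.grid = projector.grid
            self.projector = projector
        else:
            self.grid = grid if grid is not None else attenuation.grid
            self.projector = Projector(
                self.grid, system, projections.angles_deg, attenuation
            )
        if scatter_rate is not None and scatter_rate.shape != projections.counts.shape:
            raise ValueError("scatter estimate shape does not match projections")
        self.scatter_rate = scatter_rate
        if attenuation is not None and np.any(attenuation.mu > 0):
            self.support = attenuation.mu > 0
        else:
            self.support = np.ones(self.grid.shape, dtype=bool)

    def fit(
        self,
        scheme: ReconScheme,
        track_loglik: bool = False,
        initial: np.ndarray | None = None,
    ) -> OSEMResults:
        """Run OS-EM updates and snapshot the image after each iteration."""
        n_angles = self.projections.num_projections
        if scheme.num_projections != n_angles:
            raise ValueError(
                f"scheme is for {scheme.num_projections} projections, data has {n_angles}"
            )
        rates = self.projections.count_rates()
        scat = (
            self.scatter_rate
            if self.scatter_rate is not None
            else np.zeros_like(rates)
        )
        if rates.sum() == 0:
            warnings.warn("all-zero projections: returning zero image", stacklevel=2)
            zero = np.zeros(self.grid.shape)
            return OSEMResults(self, scheme, [zero.copy() for _ in range(scheme.num_iterations)])

        subsets = make_subsets(np.arange(n_angles), scheme.num_subsets)
        sens = [self.projector.subset_sensitivity(sub) for sub in subsets]

        if initial is None:
            f = np.where(self.support, 1.0, 0.0)
        else:
            f = np.asarray(initial, dtype=float).copy()
            if np.any(f < 0):
                raise ValueError("initial estimate must be nonnegative")

        iterates: list[np.ndarray] = []
        loglik: list[float] = [] if track_loglik else None
        t_per = self.projections.time_per_projection_s
        for _ in range(scheme.num_iterations):
            for sub, sens_i in zip(subsets, sens):
                q = self.projector.forward(f, sub) + scat[sub]
                floor = 1e-12 * max(q.mean(), 1e-300)
                ratio = rates[sub] / np.maximum(q, floor)
                bp = self.projector.backward(ratio, sub)
                with np.errstate(divide="ignore", invalid="ignore"):
                    upd = np.where(sens_i > 0, bp / np.where(sens_i > 0, sens_i, 1.0), 1.0)
                f = f * upd
            iterates.append(f.copy())
            if track_loglik:
                expected = (self.projector.forward(f) + scat) * t_per
                loglik.append(poisson_loglik(self.projections.counts, expected))
        return OSEMResults(self, scheme, iterates, loglik)


def osem_reconstruct(
    projections: ProjectionSet,
    attenuation: AttenuationMap | None,
    system: SystemModel,
    scheme: ReconScheme,
    scatter_estimate: np.ndarray | None = None,
    grid: Grid | None = None,
    **fit_kwargs,
) -> OSEMResults:
    """Convenience wrapper: build an :class:`OSEMModel` and fit one scheme."""
    model = OSEMModel(
        projections, attenuation, system, scatter_rate=scatter_estimate, grid=grid
    )
    return model.fit(scheme, **fit_kwargs)
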