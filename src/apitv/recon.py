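"""Iterative few-view reconstruction: ART, ASD-POCS and API-TV.

All three solvers address the constrained problem

    minimize ||f||_TV   subject to  ||M f - g|| <= eps,  f >= 0,

by interleaving data-consistency projections (Kaczmarz/ART sweeps plus a
positivity projection — the POCS phase) with steepest-descent steps on a
TV objective.  API-TV replaces the TV descent direction with the
alpha-weighted blend

    d = alpha * grad ||f - f_p||_TV + (1 - alpha) * grad ||f||_TV ,

where f_p is a prior image (typically an FBP reconstruction from a
previous dense-view scan) and alpha defaults to 0.85.  With alpha = 0
API-TV reduces exactly to ASD-POCS; with no TV phase at all it reduces
to plain ART.

The solvers are exposed statsmodels-style: a model object is built from
the data (sinogram + geometry [+ prior image]) and ``fit()`` returns a
:class:`ReconResults` carrying the image, per-iteration residual and
(when the true image is supplied) error histories, and a ``summary()``.
Thin functional wrappers (``api_tv_reconstruct`` etc.) are provided for
script use.

Main loop (one iteration): I ART sweeps -> positivity projection -> K TV
gradient-descent steps.  The TV step magnitude follows the adaptive
ASD-POCS convention: step = c * ||Delta f_ART||_2 with c decaying each
main loop, so the regularization strength tracks the progress of the
data-consistency phase.  The loop stops after ``n_main`` iterations or
as soon as the data residual drops to ``epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .geometry import ScanGeometry
from .grids import ImageGrid
from .metrics import image_error
from .projector import Sinogram, forward_project, row_norms
from .tv import TVParams, blended_tv_gradient

__all__ = [
    "ReconParams",
    "ReconResults",
    "ART",
    "ASDPOCS",
    "APITV",
    "art_sweep",
    "enforce_positivity",
    "tv_descent_phase",
    "api_tv_reconstruct",
    "asd_pocs_reconstruct",
    "art_reconstruct",
]


@dataclass(frozen=True)
class ReconParams:
    """Tuning parameters shared by the iterative solvers.

    alpha          prior blend weight in [0, 1]; 0 disables the prior term.
    lambda_art     ART relaxation in (0, 2).
    n_art          inner ART sweeps (I) per main loop.
    n_tv           inner TV descent steps (K) per main loop.
    n_main         main-loop iteration count.
    tv_step_rule   "art-scaled": step = tv_step * decay^m * ||Delta f_ART||;
                   "fixed": step = tv_step.
    tv_step        step scale factor (art-scaled) or magnitude (fixed).
    tv_step_decay  per-main-loop decay of the art-scaled step.
    epsilon        data-residual stopping tolerance (0 = run n_main loops).
    tau            TV gradient smoothing constant.
    ray_order      "sequential" (by view then detector) or "shuffle".
    seed           seed for the shuffled ray order.
    """

    alpha: float = 0.85
    lambda_art: float = 1.0
    n_art: int = 1
    n_tv: int = 10
    n_main: int = 50
    tv_step_rule: str = "art-scaled"
    tv_step: float = 0.2
    tv_step_decay: float = 0.95
    epsilon: float = 0.0
    tau: float = 1e-8
    ray_order: str = "sequential"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 < self.lambda_art < 2.0:
            raise ValueError("lambda_art must lie in (0, 2)")
        if self.n_art < 1 or self.n_main < 1:
            raise ValueError("n_art and n_main must be >= 1")
        if self.n_tv < 0:
            raise ValueError("n_tv must be >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.tv_step_rule not in ("art-scaled", "fixed"):
            raise ValueError("tv_step_rule must be 'art-scaled' or 'fixed'")
        if self.ray_order not in ("sequential", "shuffle"):
            raise ValueError("ray_order must be 'sequential' or 'shuffle'")


@dataclass
class ReconResults:
    """Result of one reconstruction run.

    ``image`` is the final iterate with positivity enforced, stored in
    single precision; histories are recorded once per main loop on the
    raw iterate (double-precision accumulation throughout).
    """

    image: ImageGrid
    residual_history: np.ndarray
    error_history: Optional[np.ndarray]
    iterations_run: int
    algorithm: str
    params: ReconParams

    def __post_init__(self) -> None:
        if len(self.residual_history) != self.iterations_run:
            raise ValueError("residual history length != iterations_run")
        if self.error_history is not None and len(self.error_history) != self.iterations_run:
            raise ValueError("error history length != iterations_run")

    @property
    def final_residual(self) -> float:
        return float(self.residual_history[-1])

    @property
    def final_error(self) -> Optional[float]:
        if self.error_history is None:
            return None
        return float(self.error_history[-1])

    def profile(self, row: int) -> np.ndarray:
        from .metrics import extract_profile

        return extract_profile(self.image, row)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"{self.algorithm} reconstruction results",
            "=" * 40,
            f"image size:          {self.image.n} x {self.image.n}"
            f"  (pixel {self.image.pixel_size:g} mm)",
            f"main iterations run: {self.iterations_run}",
            f"final residual:      {self.final_residual:.6g}",
        ]
        if self.final_error is not None:
            lines.append(f"final image error:   {self.final_error:.6g}")
        lines += [
            "-" * 40,
            f"alpha={p.alpha:g}  lambda_art={p.lambda_art:g}  "
            f"I={p.n_art}  K={p.n_tv}",
            f"tv_step_rule={p.tv_step_rule}  tv_step={p.tv_step:g}  "
            f"decay={p.tv_step_decay:g}",
            f"epsilon={p.epsilon:g}  tau={p.tau:g}  ray_order={p.ray_order}",
        ]
        return "\n".join(lines)

    def plot_convergence(self, ax=None, label: Optional[str] = None):
        """Plot the image-error history (requires truth at fit time)."""
        import matplotlib.pyplot as plt

        from .metrics import convergence_curve

        curve = convergence_curve(self)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve["iteration"], curve["error"], label=label or self.algorithm)
        ax.set_xlabel("iteration")
        ax.set_ylabel("image error")
        return ax


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def enforce_positivity(img: ImageGrid) -> ImageGrid:
    """Projection onto the nonnegativity constraint set: max(f, 0)."""
    return ImageGrid(np.maximum(img.data, 0.0), img.pixel_size)


def art_sweep(
    img: ImageGrid,
    sino: Sinogram,
    geom: Optional[ScanGeometry] = None,
    lambda_art: float = 1.0,
    order: Optional[np.ndarray] = None,
    ray_norms: Optional[np.ndarray] = None,
) -> ImageGrid:
    """One full Kaczmarz pass: for each ray j (in `order`),

        f <- f + lambda * (g_j - <M_j, f>) / ||M_j||^2 * M_j .

    Rays with zero row norm (missing the grid) are skipped.
    Returns a new image; the input is not modified.
    """
    geom = geom or sino.geom
    if img.n != geom.image_n:
        raise ValueError("image size inconsistent with geometry")
    if sino.data.shape != (geom.n_views, geom.n_det):
        raise ValueError("sinogram shape inconsistent with geometry")
    if ray_norms is None:
        ray_norms = row_norms(geom)
    if order is None:
        order = np.arange(geom.n_rays, dtype=np.int64)
    out = np.ascontiguousarray(img.data, dtype=np.float64).copy()
    _kernels.art_sweep_kernel(
        out,
        np.ascontiguousarray(sino.data, dtype=np.float64),
        ray_norms,
        np.ascontiguousarray(order, dtype=np.int64),
        geom.angles,
        geom.sod,
        geom.sdd,
        geom.n_det,
        geom.det_pitch,
        geom.image_n,
        geom.pixel_size,
        lambda_art,
    )
    return ImageGrid(out, img.pixel_size)


def tv_descent_phase(
    img: ImageGrid,
    prior: Optional[ImageGrid],
    params: ReconParams,
    step_size: float,
) -> ImageGrid:
    """K steps of normalized TV gradient descent,
    f <- f - step * d / ||d||, with the alpha-blended direction d.

    A zero gradient (or zero step) leaves the image unchanged.
    """
    if step_size < 0:
        raise ValueError("step_size must be >= 0")
    f = img.data.astype(np.float64, copy=True)
    if step_size == 0.0 or params.n_tv == 0:
        return ImageGrid(f, img.pixel_size)
    tvp = TVParams(tau=params.tau)
    fp = None if prior is None else np.asarray(prior.data, dtype=np.float64)
    zeros = np.zeros_like(f)
    for _ in range(params.n_tv):
        d = blended_tv_gradient(f, fp if fp is not None else zeros, params.alpha, tvp)
        nd = np.linalg.norm(d)
        if nd == 0.0:
            break
        f -= step_size * d / nd
    return ImageGrid(f, img.pixel_size)


# ---------------------------------------------------------------------------
# model objects
# ---------------------------------------------------------------------------


class _IterativeModel:
    """Shared machinery for the iterative reconstructors."""

    algorithm = "iterative"
    _use_tv = True

    def __init__(
        self,
        sinogram: Sinogram,
        geometry: Optional[ScanGeometry] = None,
        prior: Optional[ImageGrid] = None,
        params: Optional[ReconParams] = None,
        truth: Optional[ImageGrid] = None,
    ) -> None:
        self.geometry = geometry or sinogram.geom
        if sinogram.data.shape != (self.geometry.n_views, self.geometry.n_det):
            raise ValueError("sinogram shape inconsistent with geometry")
        self.sinogram = sinogram
        self.params = params or ReconParams()
        self.prior = prior
        self.truth = truth
        for name, image in (("prior", prior), ("truth", truth)):
            if image is not None and image.n != self.geometry.image_n:
                raise ValueError(
                    f"{name} image side {image.n} does not match "
                    f"reconstruction grid {self.geometry.image_n}"
                )

    # Subclasses pin parameters that define the algorithm.
    def _effective_params(self) -> ReconParams:
        return self.params

    def fit(self, callback=None) -> ReconResults:
        """Run the main loop and return a :class:`ReconResults`.

        ``callback(iteration, image, residual, error)`` is invoked after
        every main loop if given.
        """
        params = self._effective_params()
        geom = self.geometry
        g = np.ascontiguousarray(self.sinogram.data, dtype=np.float64)
        norms = row_norms(geom)
        truth_data = None if self.truth is None else np.asarray(self.truth.data, float)

        f = ImageGrid(np.zeros((geom.image_n, geom.image_n)), geom.pixel_size)
        prior = self.prior if params.alpha > 0 else None
        rng = np.random.default_rng(params.seed) if params.ray_order == "shuffle" else None

        residuals: list[float] = []
        errors: list[float] = []
        step_scale = params.tv_step
        for it in range(params.n_main):
            f_before = f.data.copy()
            for _ in range(params.n_art):
                if rng is not None:
                    order = rng.permutation(geom.n_rays).astype(np.int64)
                else:
                    order = np.arange(geom.n_rays, dtype=np.int64)
                f = art_sweep(f, self.sinogram, geom, params.lambda_art, order, norms)
            f = enforce_positivity(f)

            if self._use_tv and params.n_tv > 0:
                if params.tv_step_rule == "art-scaled":
                    dp = float(np.linalg.norm(f.data - f_before))
                    step = step_scale * dp
                else:
                    step = step_scale
                f = tv_descent_phase(f, prior, params, step)
                step_scale *= params.tv_step_decay if params.tv_step_rule == "art-scaled" else 1.0

            residual = float(np.linalg.norm(forward_project(f, geom).data - g))
            residuals.append(residual)
            err = None
            if truth_data is not None:
                err = image_error(f.data, truth_data)
                errors.append(err)
            if callback is not None:
                callback(it + 1, f, residual, err)
            if residual <= params.epsilon:
                break

        final = enforce_positivity(f).astype(np.float32)
        return ReconResults(
            image=ImageGrid(final.data, geom.pixel_size),
            residual_history=np.asarray(residuals),
            error_history=np.asarray(errors) if truth_data is not None else None,
            iterations_run=len(residuals),
            algorithm=self.algorithm,
            params=params,
        )


class APITV(_IterativeModel):
    """Adaptive prior-image TV reconstruction.

    The TV descent direction blends the TV gradient of the image with the
    TV gradient of its difference from the prior; ``alpha = 0`` (or no
    prior) reduces exactly to :class:`ASDPOCS`.
    """

    algorithm = "API-TV"

    def __init__(self, sinogram, geometry=None, prior=None, params=None, truth=None):
        super().__init__(sinogram, geometry, prior, params, truth)
        if self.prior is None and self.params.alpha > 0:
            raise ValueError("API-TV with alpha > 0 requires a prior image")


class ASDPOCS(_IterativeModel):
    """TV-constrained reconstruction without a prior (ART/POCS sweeps
    interleaved with adaptive steepest-descent steps on plain TV)."""

    algorithm = "ASD-POCS"

    def _effective_params(self) -> ReconParams:
        return replace(self.params, alpha=0.0)


class ART(_IterativeModel):
    """Plain algebraic reconstruction: ART sweeps + positivity, no TV."""

    algorithm = "ART"
    _use_tv = False

    def _effective_params(self) -> ReconParams:
        return replace(self.params, alpha=0.0, n_tv=0)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def api_tv_reconstruct(
    sino: Sinogram,
    geom: Optional[ScanGeometry] = None,
    prior: Optional[ImageGrid] = None,
    params: Optional[ReconParams] = None,
    truth: Optional[ImageGrid] = None,
) -> ReconResults:
    """Run API-TV (see :class:`APITV`) and return its results."""
    return APITV(sino, geom, prior=prior, params=params, truth=truth).fit()


def asd_pocs_reconstruct(
    sino: Sinogram,
    geom: Optional[ScanGeometry] = None,
    params: Optional[ReconParams] = None,
    truth: Optional[ImageGrid] = None,
) -> ReconResults:
    """Run ASD-POCS — identical to API-TV with alpha forced to 0."""
    return ASDPOCS(sino, geom, params=params, truth=truth).fit()


def art_reconstruct(
    sino: Sinogram,
    geom: Optional[ScanGeometry] = None,
    params: Optional[ReconParams] = None,
    truth: Optional[ImageGrid] = None,
) -> ReconResults:
    """Run plain ART (sweeps + positivity, no TV phase)."""
    return ART(sino, geom, params=params, truth=truth).fit()
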