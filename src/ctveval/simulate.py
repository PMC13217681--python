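"""Synthetic contouring cohorts for end-to-end pipeline testing.

No delineation study deposits its observer contours, so this module
fabricates one: a deterministic pelvic-CTV-scale reference volume (an
ellipsoid, optionally with nodal side-lobes, of roughly 650 cm3 on a
5 mm-slice grid), per-observer pre- and post-training contours produced by
stochastic perturbation of the reference, and 5-point Likert questionnaire
responses with a positive post-training shift.

Perturbation model
------------------
An observer's contour differs from the reference in three observable
ways, each mapped to one severity knob and one metric family:

* rigid mislocalisation — a random per-axis translation (normal with SD
  ``translation_sd`` mm), visible in the centre-of-mass distance;
* systematic over-/under-contouring — a uniform boundary shift of
  ``boundary_growth`` mm (dilation when positive, erosion when negative),
  visible in the relative volume difference;
* local boundary disagreement — a smooth random radial displacement of
  the surface with SD ``surface_noise_sd`` mm and a fixed spatial
  correlation length, visible in ASD and the percentile Hausdorff
  distance.

All three operate on the signed Euclidean distance field of the reference
(negative inside), where they are exact level-set operations: translating
the field translates the contour, subtracting g mm from the field grows
the contour by g mm everywhere, and adding a smooth noise field displaces
the boundary radially by the local noise value.

Reproducibility
---------------
Every output is a pure function of its spec including the seed.  Observer
sub-seeds derive from the master seed through ``numpy`` spawn keys indexed
by (observer, phase), so adding an observer never reshuffles the data of
earlier observers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cohort import MaskRecord
from .exceptions import DegenerateOutputError, InvalidGeometryError
from .mask import VoxelMask
from .stats import LikertRecord

__all__ = [
    "GridSpec",
    "Ellipsoid",
    "ReferenceShape",
    "PerturbationSpec",
    "CohortSpec",
    "make_reference_mask",
    "signed_distance",
    "translate_mask",
    "perturb_mask",
    "simulate_cohort",
    "simulate_likert",
]

#: Spatial correlation length (mm) of the radial boundary jitter.  Chosen
#: at the scale of the anatomical features observers disagree on (a couple
#: of centimetres); much shorter would model voxel noise, much longer a
#: rigid deformation.
NOISE_CORRELATION_MM = 20.0

#: Default questionnaire items: one global confidence item plus the four
#: CTV subregions rated for delineation proficiency.
DEFAULT_LIKERT_ITEMS = ("confidence", "CTV-U", "CTV-C", "CTV-Np", "CTV-Na")


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid: array shape and physical spacing (mm).

    Axis 0 is the slice axis.  The default echoes the study geometry:
    5 mm slices with fine in-plane resolution, at an extent that holds a
    pelvic CTV.
    """

    shape: tuple[int, int, int] = (60, 160, 160)
    spacing: tuple[float, float, float] = (5.0, 1.25, 1.25)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center_mm(self) -> tuple[float, float, float]:
        return tuple(
            o + (n - 1) * s / 2.0
            for o, n, s in zip(self.origin, self.shape, self.spacing)
        )


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: semi-axes (mm) and centre offset from the
    grid centre (mm)."""

    semi_axes: tuple[float, float, float]
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)


#: Default reference anatomy: a central body (uterus/cervix block) flanked
#: by two elongated lateral lobes standing in for the pelvic nodal
#: volumes.  The lobes raise the surface-to-volume ratio the way real
#: nodal CTVs do, so boundary noise moves DSC at realistic rates; the
#: union volume lands near the ~650 cm3 scale of a whole pelvic CTV.
_DEFAULT_BODY = Ellipsoid(semi_axes=(55.0, 44.0, 46.0))
_DEFAULT_LOBES = (
    Ellipsoid(semi_axes=(55.0, 20.0, 23.0), offset=(0.0, 0.0, 56.0)),
    Ellipsoid(semi_axes=(55.0, 20.0, 23.0), offset=(0.0, 0.0, -56.0)),
)


@dataclass(frozen=True)
class ReferenceShape:
    """Base ellipsoid plus optional nodal side-lobes."""

    body: Ellipsoid = _DEFAULT_BODY
    lobes: tuple[Ellipsoid, ...] = _DEFAULT_LOBES

    def components(self) -> tuple[Ellipsoid, ...]:
        return (self.body, *self.lobes)

    def analytic_volume_cm3(self) -> float:
        """Sum of component ellipsoid volumes (ignores any overlap)."""
        return sum(
            4.0 / 3.0 * np.pi * np.prod(e.semi_axes) / 1000.0
            for e in self.components()
        )


@dataclass(frozen=True)
class PerturbationSpec:
    """Severity of one phase's contouring errors.

    ``translation_sd`` and ``surface_noise_sd`` are non-negative SDs in
    mm; ``boundary_growth`` is a signed uniform boundary shift in mm
    (dilation > 0, erosion < 0).
    """

    translation_sd: float = 0.0
    boundary_growth: float = 0.0
    surface_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.translation_sd < 0 or self.surface_noise_sd < 0:
            raise InvalidGeometryError(
                "translation_sd and surface_noise_sd must be non-negative"
            )

    def is_identity(self) -> bool:
        return (
            self.translation_sd == 0
            and self.boundary_growth == 0
            and self.surface_noise_sd == 0
        )


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic training cohort.

    Defaults emulate the study conditions of a contouring course: 19
    observers on a ~650 cm3 reference at 5 mm slices, pre-training
    perturbations clearly more severe than post-training (training halves
    each severity, moving mean DSC from the low 0.80s towards the
    reference), and a 5-point Likert questionnaire whose latent mean
    shifts up by about 0.9 points after training.
    """

    n_observers: int = 19
    pre: PerturbationSpec = PerturbationSpec(
        translation_sd=4.0, boundary_growth=0.0, surface_noise_sd=10.0
    )
    post: PerturbationSpec = PerturbationSpec(
        translation_sd=2.0, boundary_growth=0.0, surface_noise_sd=5.0
    )
    reference_shape: ReferenceShape = ReferenceShape()
    grid: GridSpec = GridSpec()
    case_id: str = "case1"
    structure: str = "CTV"
    likert_items: tuple[str, ...] = DEFAULT_LIKERT_ITEMS
    likert_pre_mean: float = 3.4
    likert_shift: float = 0.9
    likert_sd: float = 0.9

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise InvalidGeometryError("a cohort needs at least 2 observers")

    @staticmethod
    def small(**overrides) -> "CohortSpec":
        """A coarse-grid preset for simulation studies.

        Keeps the 5 mm slices and the study-scale severities but uses a
        2.5 mm in-plane grid and an anatomy scaled to 80% linearly
        (~340 cm3) so that thousands of masks can be generated and scored
        quickly in simulation studies.
        """
        k = 0.8
        base = dict(
            grid=GridSpec(shape=(22, 56, 56), spacing=(5.0, 2.5, 2.5)),
            reference_shape=ReferenceShape(
                body=Ellipsoid(
                    semi_axes=tuple(k * a for a in _DEFAULT_BODY.semi_axes)
                ),
                lobes=tuple(
                    Ellipsoid(
                        semi_axes=tuple(k * a for a in lobe.semi_axes),
                        offset=tuple(k * o for o in lobe.offset),
                    )
                    for lobe in _DEFAULT_LOBES
                ),
            ),
        )
        base.update(overrides)
        return CohortSpec(**base)


def make_reference_mask(
    shape: ReferenceShape, grid: GridSpec
) -> VoxelMask:
    """Deterministic reference mask: union of ellipsoids voxelised on the grid.

    A voxel is foreground when its centre lies inside any component
    ellipsoid.  Raises if any component has a non-positive semi-axis or
    extends beyond the grid.
    """
    center = np.asarray(grid.center_mm)
    coords = [
        o + np.arange(n) * s
        for o, n, s in zip(grid.origin, grid.shape, grid.spacing)
    ]
    lo = np.asarray([c[0] for c in coords])
    hi = np.asarray([c[-1] for c in coords])

    occ = np.zeros(grid.shape, dtype=bool)
    for e in shape.components():
        axes = np.asarray(e.semi_axes, dtype=float)
        if np.any(axes <= 0):
            raise InvalidGeometryError(
                f"ellipsoid semi-axes must be strictly positive, got {e.semi_axes}"
            )
        c = center + np.asarray(e.offset)
        if np.any(c - axes < lo) or np.any(c + axes > hi):
            raise InvalidGeometryError(
                f"ellipsoid (semi-axes {e.semi_axes}, centre {tuple(c)}) "
                "extends beyond the grid"
            )
        z = (coords[0] - c[0]) / axes[0]
        y = (coords[1] - c[1]) / axes[1]
        x = (coords[2] - c[2]) / axes[2]
        occ |= (
            z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
        ) <= 1.0
    return VoxelMask(occ, grid.spacing, grid.origin)


def _distance_to_boundary(region: np.ndarray, spacing) -> np.ndarray:
    """Distance (mm) from voxel centres outside ``region`` to its boundary.

    A plain Euclidean distance transform measures centre-to-centre
    distances, overestimating the distance to the region *boundary* (which
    runs midway between opposite-phase voxel centres) by up to half a
    voxel.  Here the half-extent of a voxel along the direction to the
    nearest in-region voxel is subtracted — exact for axis-aligned
    neighbours, a tight approximation otherwise — so that level sets of
    the field track the geometric boundary at sub-voxel precision.
    """
    s = np.asarray(spacing, dtype=float).reshape(3, 1, 1, 1)
    dist, idx = ndimage.distance_transform_edt(
        ~region, sampling=spacing, return_indices=True
    )
    delta = (np.indices(region.shape) - idx) * s
    norm = np.sqrt((delta**2).sum(axis=0))
    safe = np.maximum(norm, 1e-12)
    half_extent = 0.5 * (np.abs(delta / safe) * s).sum(axis=0)
    out = np.maximum(norm - half_extent, 1e-9)
    out[region] = 0.0
    return out


def signed_distance(mask: VoxelMask) -> np.ndarray:
    """Signed distance (mm) to the mask boundary, negative inside.

    Thresholding at ``<= 0`` reproduces the original occupancy exactly;
    thresholding at ``<= g`` grows the contour by g mm at sub-voxel
    accuracy (the field is boundary-consistent, see
    :func:`_distance_to_boundary`).
    """
    occ = mask.occupancy
    return _distance_to_boundary(occ, mask.spacing) - _distance_to_boundary(
        ~occ, mask.spacing
    )


def _shift_field(field_: np.ndarray, offset_mm, spacing) -> np.ndarray:
    shift_vox = np.asarray(offset_mm, dtype=float) / np.asarray(spacing)
    return ndimage.shift(field_, shift_vox, order=1, mode="nearest")


def translate_mask(mask: VoxelMask, offset_mm, sdf: np.ndarray | None = None) -> VoxelMask:
    """Translate a mask by a physical offset (mm), sub-voxel accurate.

    Implemented by linearly interpolating the signed distance field and
    re-thresholding, so non-integer offsets resample the boundary rather
    than rounding to whole voxels.
    """
    if sdf is None:
        sdf = signed_distance(mask)
    shifted = _shift_field(sdf, offset_mm, mask.spacing)
    occ = shifted <= 0.0
    if not occ.any():
        raise DegenerateOutputError("translation moved the mask off the grid")
    return mask.with_occupancy(occ)


def _smooth_noise_field(
    rng: np.random.Generator, shape, spacing, correlation_mm: float
) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = [correlation_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    sd = smooth.std()
    if sd == 0:  # pathological tiny grids
        return np.zeros(shape)
    return smooth / sd


def perturb_mask(
    ref: VoxelMask,
    spec: PerturbationSpec,
    rng: np.random.Generator | None = None,
    sdf: np.ndarray | None = None,
) -> VoxelMask:
    """One simulated observer contour: a stochastic perturbation of ``ref``.

    Applies, in order, a random rigid translation (per-axis normal with SD
    ``spec.translation_sd``), a uniform boundary shift of
    ``spec.boundary_growth`` mm, and smooth radial boundary jitter with SD
    ``spec.surface_noise_sd`` mm.  A zero-severity spec returns a mask
    identical to the reference.  With a fixed seed (or supplied generator
    state) the output is bitwise reproducible.

    ``sdf`` may carry a precomputed :func:`signed_distance` of ``ref`` to
    amortise the transform across many observers.
    """
    if ref.is_empty():
        raise DegenerateOutputError("cannot perturb an empty reference mask")
    if spec.is_identity():
        return ref.with_occupancy(ref.occupancy.copy())
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if sdf is None:
        sdf = signed_distance(ref)

    offset = rng.normal(0.0, 1.0, size=3) * spec.translation_sd
    field_ = _shift_field(sdf, offset, ref.spacing) if np.any(offset) else sdf.copy()

    field_ -= spec.boundary_growth

    if spec.surface_noise_sd > 0:
        noise = _smooth_noise_field(
            rng, ref.shape, ref.spacing, NOISE_CORRELATION_MM
        )
        field_ += spec.surface_noise_sd * noise

    occ = field_ <= 0.0
    if not occ.any():
        raise DegenerateOutputError(
            "perturbation emptied the mask (erosion/noise too severe for the shape)"
        )
    return ref.with_occupancy(occ)


def _phase_rng(master_seed: int, observer_index: int, phase_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(master_seed, spawn_key=(observer_index, phase_index))
    return np.random.default_rng(ss)


def simulate_likert(
    spec: CohortSpec, master_seed: int
) -> list[LikertRecord]:
    """Likert questionnaire with a positive post-training latent shift.

    Each observer x item score is an independent draw from a latent
    normal (mean ``likert_pre_mean``, SD ``likert_sd``; post adds
    ``likert_shift``), rounded to the nearest integer and clipped to
    [1, 5] — so outputs are always valid 5-point responses whatever the
    latent parameters.
    """
    records = []
    for i in range(spec.n_observers):
        rng = _phase_rng(master_seed, i, 2)
        observer_id = f"obs{i + 1:02d}"
        for item in spec.likert_items:
            latent_pre = rng.normal(spec.likert_pre_mean, spec.likert_sd)
            latent_post = rng.normal(
                spec.likert_pre_mean + spec.likert_shift, spec.likert_sd
            )
            records.append(
                LikertRecord(
                    observer_id=observer_id,
                    item_id=item,
                    pre=int(np.clip(np.rint(latent_pre), 1, 5)),
                    post=int(np.clip(np.rint(latent_post), 1, 5)),
                )
            )
    return records


def simulate_cohort(
    spec: CohortSpec, master_seed: int
) -> tuple[VoxelMask, list[MaskRecord], list[LikertRecord]]:
    """Generate a full synthetic cohort.

    Returns the reference mask, one pre and one post mask record per
    observer (independent sub-seeds per observer and phase), and the
    Likert table.  The whole output is a pure function of
    ``(spec, master_seed)``.
    """
    ref = make_reference_mask(spec.reference_shape, spec.grid)
    sdf = signed_distance(ref)
    records: list[MaskRecord] = []
    for i in range(spec.n_observers):
        observer_id = f"obs{i + 1:02d}"
        for phase_index, (phase, pspec) in enumerate(
            (("pre", spec.pre), ("post", spec.post))
        ):
            rng = _phase_rng(master_seed, i, phase_index)
            try:
                mask = perturb_mask(ref, pspec, rng=rng, sdf=sdf)
            except DegenerateOutputError as exc:
                raise DegenerateOutputError(
                    f"observer {observer_id}, phase {phase}: {exc}"
                ) from exc
            records.append(
                MaskRecord(
                    observer_id=observer_id,
                    case_id=spec.case_id,
                    phase=phase,
                    structure=spec.structure,
                    mask=mask,
                )
            )
    likert = simulate_likert(spec, master_seed)
    return ref, records, likert
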