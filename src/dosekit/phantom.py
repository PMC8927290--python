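"""Synthetic pelvic phantoms, plans, and analytic ground-truth doses.

This module emulates a catalog of cervical-cancer IMRT plans so the rest
of the toolkit can be exercised without clinical data: an elliptical body
with a central spherical PTV and six normal structures (bladder anterior,
rectum and spinal cord posterior, femoral heads lateral), plans with 7 or
9 coplanar beams at fixed or jittered gantry angles in supine or prone
position, and a deliberately simple dose engine — per beam, dose along
each source ray is ``weight * exp(-mu * depth-in-body) * aperture
profile`` (1 inside the BEV aperture, linear rolloff over the penumbra),
summed over beams and globally scaled so the PTV mean equals the
prescription (50.4 Gy).  The engine is not a clinical algorithm; its job
is to make dose a deterministic, beam-setting-dependent function of
anatomy so that beam-setting effects are learnable.

Prone position is modeled by flipping the phantom anterior-posterior and
left-right relative to the fixed gantry frame, which reproduces the
geometric relationship change between beams and anatomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .beam_mask import (
    bev_aperture,
    combined_beam_mask,
    project_to_aperture_plane,
    source_position,
)
from .data_prep import assemble_sample, normalize_ct, TrainingSample
from .grid import VoxelGrid
from .plans import DEFAULT_PRESCRIPTION_GY, REFERENCE_7_ANGLES, PlanSpec
from .structures import StructureSet

__all__ = [
    "PhantomParams",
    "Phantom",
    "DoseEngineParams",
    "DatasetStratum",
    "DatasetSpec",
    "SyntheticDataset",
    "generate_phantom",
    "generate_plan",
    "synth_dose",
    "generate_dataset",
]

#: desk-scale default grid: 64 x 64 x 32 voxels at 2.5 mm
DEFAULT_SHAPE = (64, 64, 32)
DEFAULT_SPACING = (2.5, 2.5, 2.5)


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of one synthetic pelvis.

    All positions are mm in the patient frame with the PTV region near the
    grid center; y increases toward posterior.  HU values are means with a
    shared additive Gaussian noise of ``noise_sd_hu``.
    """

    body_semiaxes_mm: tuple[float, float, float] = (70.0, 55.0, 300.0)
    #: posterior shift of the body outline relative to the isocenter; makes
    #: the pelvis anterior-posterior asymmetric (thinner anterior wall), so
    #: patient position genuinely changes radiological depths
    body_ap_offset_mm: float = 6.0
    ptv_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ptv_radius_mm: float = 20.0
    bladder_center_mm: tuple[float, float, float] = (0.0, -29.0, 0.0)
    bladder_radius_mm: float = 13.0
    rectum_center_mm: tuple[float, float] = (0.0, 28.0)
    rectum_radius_mm: float = 8.0
    rectum_halflength_mm: float = 35.0
    femoral_head_radius_mm: float = 12.0
    femoral_head_offset_mm: tuple[float, float] = (45.0, 5.0)
    cord_center_mm: tuple[float, float] = (0.0, 42.0)
    cord_radius_mm: float = 5.0
    hu_means: dict = field(
        default_factory=lambda: {
            "body": 30.0,
            "ptv": 45.0,
            "bladder": 0.0,
            "rectum": 15.0,
            "femoral_head": 400.0,
            "spinal_cord": 35.0,
            "air": -1000.0,
        }
    )
    noise_sd_hu: float = 15.0
    seed: int = 0
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        radii = (
            self.ptv_radius_mm,
            self.bladder_radius_mm,
            self.rectum_radius_mm,
            self.femoral_head_radius_mm,
            self.cord_radius_mm,
        )
        if any(r <= 0 for r in radii) or any(a <= 0 for a in self.body_semiaxes_mm):
            raise ValueError("all radii and body semi-axes must be positive")


@dataclass
class Phantom:
    """A generated phantom: CT, structures, grid, and its analytic body.

    ``body_center_mm``/``body_semiaxes_mm`` describe the body ellipsoid in
    world coordinates after any prone flip, so the dose engine can compute
    radiological depth by exact ray-ellipsoid intersection.
    """

    ct_hu: np.ndarray
    structures: StructureSet
    grid: VoxelGrid
    params: PhantomParams
    position: str = "supine"
    body_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def body_semiaxes_mm(self) -> tuple[float, float, float]:
        return self.params.body_semiaxes_mm


def _sphere(centers: np.ndarray, c, r: float) -> np.ndarray:
    return ((centers - np.asarray(c)) ** 2).sum(axis=-1) <= r * r


def _zcyl(centers: np.ndarray, cx: float, cy: float, r: float, zc=None, hl=None) -> np.ndarray:
    m = (centers[..., 0] - cx) ** 2 + (centers[..., 1] - cy) ** 2 <= r * r
    if hl is not None:
        m &= np.abs(centers[..., 2] - zc) <= hl
    return m


def generate_phantom(
    params: PhantomParams | None = None,
    position: str = "supine",
) -> Phantom:
    """Build the CT volume and seven-ROI structure set of one phantom.

    Deterministic given ``params.seed``.  Raises if any ROI escapes the
    body under the requested geometry.
    """
    params = params or PhantomParams()
    if position not in ("supine", "prone"):
        raise ValueError(f"position must be supine|prone, got {position!r}")
    grid = VoxelGrid.centered(params.shape, params.spacing_mm)
    centers = grid.voxel_centers()
    zc = float(grid.center_mm()[2])

    a, b, c = params.body_semiaxes_mm
    body_center = np.array([0.0, params.body_ap_offset_mm, zc])
    rel = (centers - body_center) / np.array([a, b, c])
    body = (rel**2).sum(axis=-1) <= 1.0

    ptv = _sphere(centers, params.ptv_center_mm, params.ptv_radius_mm)
    bladder = _sphere(centers, params.bladder_center_mm, params.bladder_radius_mm)
    rectum = _zcyl(
        centers,
        *params.rectum_center_mm,
        params.rectum_radius_mm,
        zc=zc,
        hl=params.rectum_halflength_mm,
    )
    fx, fy = params.femoral_head_offset_mm
    fem_l = _sphere(centers, (fx, fy, 0.0), params.femoral_head_radius_mm)
    fem_r = _sphere(centers, (-fx, fy, 0.0), params.femoral_head_radius_mm)
    cord = _zcyl(centers, *params.cord_center_mm, params.cord_radius_mm)

    rois = {
        "bladder": bladder,
        "femoral_head_l": fem_l,
        "femoral_head_r": fem_r,
        "ptv": ptv,
        "rectum": rectum,
        "spinal_cord": cord,
    }
    for name, mask in rois.items():
        if (mask & ~body).any():
            raise ValueError(f"ROI {name!r} escapes the body under the requested geometry")

    hu = np.full(grid.shape, params.hu_means["air"])
    hu[body] = params.hu_means["body"]
    hu[rectum] = params.hu_means["rectum"]
    hu[bladder] = params.hu_means["bladder"]
    hu[fem_l | fem_r] = params.hu_means["femoral_head"]
    hu[cord] = params.hu_means["spinal_cord"]
    hu[ptv] = params.hu_means["ptv"]
    if params.noise_sd_hu > 0:
        rng = np.random.default_rng(params.seed)
        hu = hu + rng.normal(0.0, params.noise_sd_hu, size=grid.shape)

    if position == "prone":
        # anatomy flips anterior<->posterior and left<->right in the fixed
        # gantry frame; the centered grid is mirror-symmetric about its center
        hu = hu[::-1, ::-1, :].copy()
        rois = {k: v[::-1, ::-1, :].copy() for k, v in rois.items()}
        body = body[::-1, ::-1, :].copy()
        gc = grid.center_mm()
        body_center = np.array(
            [2 * gc[0] - body_center[0], 2 * gc[1] - body_center[1], body_center[2]]
        )
    rois["body"] = body
    structures = StructureSet(masks=rois, grid=grid)
    return Phantom(
        ct_hu=hu,
        structures=structures,
        grid=grid,
        params=params,
        position=position,
        body_center_mm=tuple(body_center),
    )


#: the fixed clinical 9-field arrangement: equispaced every 40 deg
REFERENCE_9_ANGLES = tuple(float(a) for a in range(0, 360, 40))


def generate_plan(
    seed: int,
    beam_count: int = 7,
    angle_policy: str = "fixed",
    position: str = "supine",
    jitter_deg: float = 15.0,
    isocenter=(0.0, 0.0, 0.0),
    prescription_gy: float = DEFAULT_PRESCRIPTION_GY,
) -> PlanSpec:
    """Draw one plan's beam settings.

    ``angle_policy="fixed"`` returns the named clinical arrangement (the
    7-field 0/50/100/150/210/260/310 set, or 9 fields every 40 deg);
    ``"jittered"`` perturbs each equispaced base angle by a seeded uniform
    offset within ``+-jitter_deg`` to create non-homogeneous catalogs.
    """
    if beam_count not in (7, 9):
        raise ValueError("beam_count must be 7 or 9")
    if angle_policy == "fixed":
        angles = REFERENCE_7_ANGLES if beam_count == 7 else REFERENCE_9_ANGLES
    elif angle_policy == "jittered":
        base = np.arange(beam_count) * (360.0 / beam_count)
        rng = np.random.default_rng(seed)
        angles = tuple((base + rng.uniform(-jitter_deg, jitter_deg, beam_count)) % 360.0)
    else:
        raise ValueError(f"angle_policy must be fixed|jittered, got {angle_policy!r}")
    return PlanSpec(
        angles=tuple(angles),
        isocenter=tuple(isocenter),
        prescription_gy=prescription_gy,
        position=position,
    )


@dataclass(frozen=True)
class DoseEngineParams:
    """Knobs of the analytic dose engine.

    ``mu_per_mm`` is the effective linear attenuation coefficient (0.005
    /mm, roughly water at megavoltage energies); ``penumbra_mm`` the
    in-plane width of the linear dose rolloff outside the aperture;
    ``beam_weights`` per-beam relative weights (equal when None).
    """

    mu_per_mm: float = 0.005
    penumbra_mm: float = 5.0
    beam_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.mu_per_mm < 0:
            raise ValueError("mu must be >= 0")
        if self.penumbra_mm < 0:
            raise ValueError("penumbra must be >= 0")
        if self.beam_weights is not None and any(w < 0 for w in self.beam_weights):
            raise ValueError("beam weights must be >= 0")


def _ray_ellipsoid_depth(
    sources: np.ndarray,
    targets: np.ndarray,
    center: np.ndarray,
    semiaxes: np.ndarray,
) -> np.ndarray:
    """Path length (mm) traveled inside the body ellipsoid from source to
    each target point, by exact ray-ellipsoid intersection."""
    d = targets - sources
    length = np.linalg.norm(d, axis=-1)
    p0 = (sources - center) / semiaxes
    dd = d / semiaxes
    A = (dd**2).sum(axis=-1)
    B = 2.0 * (p0 * dd).sum(axis=-1)
    C = (p0**2).sum(axis=-1) - 1.0
    disc = B * B - 4 * A * C
    hit = disc > 0
    depth = np.zeros(length.shape)
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t1 = (-B - sq) / (2 * A)
    t2 = (-B + sq) / (2 * A)
    # inside-body chord clipped to [entry, target]
    lo = np.clip(t1, 0.0, 1.0)
    hi = np.clip(np.minimum(t2, 1.0), 0.0, 1.0)
    depth[hit] = (np.maximum(hi - lo, 0.0) * length)[hit]
    return depth


def synth_dose(
    phantom: Phantom,
    plan: PlanSpec,
    engine: DoseEngineParams | None = None,
) -> np.ndarray:
    """Analytic ground-truth dose for one phantom/plan pair, in Gy.

    Per beam, dose at a voxel is ``weight * exp(-mu * depth-in-body) *
    profile`` where the profile is 1 for rays inside the BEV aperture and
    rolls off linearly to 0 over the penumbra width outside it; beams are
    summed and the total is scaled so the PTV mean equals the plan's
    prescription.  The field therefore depends on the beam angles (through
    both aperture orientation and radiological depth), is nonnegative, and
    vanishes outside every beam's aperture-plus-penumbra.
    """
    engine = engine or DoseEngineParams()
    ptv = phantom.structures["ptv"]
    if not ptv.any():
        raise ValueError("PTV mask is empty")
    grid = phantom.grid
    iso = np.asarray(plan.isocenter, dtype=float)
    centers = grid.voxel_centers().reshape(-1, 3)
    weights = engine.beam_weights or (1.0,) * plan.beam_count
    if len(weights) != plan.beam_count:
        raise ValueError("beam_weights length must equal beam count")
    body_center = np.asarray(phantom.body_center_mm)
    semiaxes = np.asarray(phantom.body_semiaxes_mm)

    total = np.zeros(len(centers))
    for angle, w in zip(plan.angles, weights):
        if w == 0:
            continue
        src = source_position(angle, iso, plan.sad_mm)
        aperture = bev_aperture(src, iso, ptv, grid)
        pu, pv, forward = project_to_aperture_plane(aperture, centers)
        profile = np.zeros(len(centers))
        fwd = np.flatnonzero(forward)
        poly = aperture.polygon
        inside = shapely.intersects_xy(poly, pu[fwd], pv[fwd])
        profile[fwd[inside]] = 1.0
        if engine.penumbra_mm > 0:
            minx, miny, maxx, maxy = poly.bounds
            near = fwd[
                ~inside
                & (pu[fwd] >= minx - engine.penumbra_mm)
                & (pu[fwd] <= maxx + engine.penumbra_mm)
                & (pv[fwd] >= miny - engine.penumbra_mm)
                & (pv[fwd] <= maxy + engine.penumbra_mm)
            ]
            if len(near):
                pts = shapely.points(pu[near], pv[near])
                dist = shapely.distance(poly, pts)
                profile[near] = np.maximum(0.0, 1.0 - dist / engine.penumbra_mm)
        active = profile > 0
        if engine.mu_per_mm > 0 and active.any():
            depth = _ray_ellipsoid_depth(
                src[None, :], centers[active], body_center, semiaxes
            )
            profile[active] *= np.exp(-engine.mu_per_mm * depth)
        total += w * profile

    dose = total.reshape(grid.shape)
    ptv_mean = dose[ptv].mean()
    if ptv_mean <= 0:
        raise ValueError("no dose delivered to the PTV; check plan geometry")
    return dose * (plan.prescription_gy / ptv_mean)


# ---------------------------------------------------------------------------
# dataset catalogs


@dataclass(frozen=True)
class DatasetStratum:
    """One homogeneous slice of the emulated plan catalog."""

    name: str
    count: int
    beam_count: int
    angle_policy: str
    position: str
    role: str  # train | test


#: default strata mirroring the emulated clinical catalog: 46 fixed-angle
#: supine 7-beam, 167 jittered 7-beam, 21 nine-beam, 45 prone (train pool
#: of 279) plus 9/12/13 held-out test cases per experiment family
DEFAULT_STRATA = (
    DatasetStratum("fixed7_supine", 46, 7, "fixed", "supine", "train"),
    DatasetStratum("jitter7_supine", 167, 7, "jittered", "supine", "train"),
    DatasetStratum("nine_supine", 21, 9, "jittered", "supine", "train"),
    DatasetStratum("prone7", 45, 7, "jittered", "prone", "train"),
    DatasetStratum("fixed7_supine_test", 9, 7, "fixed", "supine", "test"),
    DatasetStratum("nine_supine_test", 12, 9, "jittered", "supine", "test"),
    DatasetStratum("prone7_test", 13, 7, "jittered", "prone", "test"),
)


@dataclass(frozen=True)
class DatasetSpec:
    """Catalog composition: strata, grid, engine, and phantom variability."""

    strata: tuple[DatasetStratum, ...] = DEFAULT_STRATA
    scale: float = 1.0
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    jitter_deg: float = 15.0
    engine: DoseEngineParams = field(default_factory=DoseEngineParams)

    def scaled_counts(self) -> dict[str, int]:
        return {s.name: max(1, math.ceil(s.count * self.scale)) for s in self.strata}


class SyntheticDataset:
    """A generated catalog plus lazy, cached sample construction.

    ``catalog`` is a pandas DataFrame with one row per plan (plan_id,
    stratum, role, beam_count, angles, angle_policy, position, seeds).
    ``sample(plan_id, include_beam_mask)`` builds the aligned training
    sample on demand: phantom -> analytic dose -> beam mask -> normalized
    CT -> channel stack.
    """

    def __init__(self, spec: DatasetSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        rows = []
        self._phantom_params: dict[str, PhantomParams] = {}
        self._plans: dict[str, PlanSpec] = {}
        counts = spec.scaled_counts()
        i = 0
        for stratum in spec.strata:
            for _ in range(counts[stratum.name]):
                pid = f"plan_{i:04d}"
                plan_seed = int(rng.integers(2**31))
                phantom_seed = int(rng.integers(2**31))
                plan = generate_plan(
                    plan_seed,
                    beam_count=stratum.beam_count,
                    angle_policy=stratum.angle_policy,
                    position=stratum.position,
                    jitter_deg=spec.jitter_deg,
                )
                params = self._vary_phantom(phantom_seed)
                self._plans[pid] = plan
                self._phantom_params[pid] = params
                rows.append(
                    {
                        "plan_id": pid,
                        "stratum": stratum.name,
                        "role": stratum.role,
                        "beam_count": stratum.beam_count,
                        "angles": plan.sorted_angles(),
                        "angle_policy": stratum.angle_policy,
                        "position": stratum.position,
                        "plan_seed": plan_seed,
                        "phantom_seed": phantom_seed,
                    }
                )
                i += 1
        self.catalog = pd.DataFrame(rows)
        self._cache: dict[tuple[str, bool], TrainingSample] = {}

    def _vary_phantom(self, phantom_seed: int) -> PhantomParams:
        """Per-patient anatomical variability, deterministic in the seed."""
        r = np.random.default_rng(phantom_seed)
        return PhantomParams(
            ptv_radius_mm=float(r.uniform(16.0, 24.0)),
            bladder_center_mm=(0.0, float(r.uniform(-32.0, -26.0)), 0.0),
            bladder_radius_mm=float(r.uniform(11.0, 14.0)),
            rectum_center_mm=(0.0, float(r.uniform(26.0, 31.0))),
            femoral_head_offset_mm=(float(r.uniform(43.0, 48.0)), 5.0),
            seed=phantom_seed,
            shape=self.spec.shape,
            spacing_mm=self.spec.spacing_mm,
        )

    @property
    def plan_ids(self) -> list[str]:
        return list(self.catalog["plan_id"])

    def plan(self, plan_id: str) -> PlanSpec:
        return self._plans[plan_id]

    def phantom(self, plan_id: str) -> Phantom:
        plan = self._plans[plan_id]
        return generate_phantom(self._phantom_params[plan_id], position=plan.position)

    def sample(self, plan_id: str, include_beam_mask: bool = True) -> TrainingSample:
        key = (plan_id, include_beam_mask)
        if key not in self._cache:
            phantom = self.phantom(plan_id)
            plan = self._plans[plan_id]
            dose = synth_dose(phantom, plan, self.spec.engine)
            bm = (
                combined_beam_mask(plan, phantom.structures["ptv"], phantom.grid)
                if include_beam_mask
                else None
            )
            self._cache[key] = assemble_sample(
                ct=normalize_ct(phantom.ct_hu),
                structures=phantom.structures,
                dose_gy=dose,
                grid=phantom.grid,
                beam_mask=bm,
                include_beam=include_beam_mask,
                plan=plan,
                meta={"plan_id": plan_id},
            )
        return self._cache[key]

    def samples(self, plan_ids, include_beam_mask: bool = True) -> list[TrainingSample]:
        return [self.sample(pid, include_beam_mask) for pid in plan_ids]

    def clear_cache(self) -> None:
        self._cache.clear()


def generate_dataset(
    spec: DatasetSpec | None = None,
    seed: int = 0,
    out_dir=None,
) -> SyntheticDataset:
    """Generate a seeded catalog of synthetic plans (lazily materialized).

    With ``out_dir`` set, the catalog is written as CSV and every sample
    (with beam mask) to the toolkit sample format.
    """
    ds = SyntheticDataset(spec or DatasetSpec(), seed)
    if out_dir is not None:
        from . import rt_io

        out_dir = __import__("pathlib").Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cat = ds.catalog.copy()
        cat["angles"] = cat["angles"].map(lambda t: "|".join(f"{a:.3f}" for a in t))
        cat.to_csv(out_dir / "catalog.csv", index=False)
        for pid in ds.plan_ids:
            rt_io.save_sample(ds.sample(pid, include_beam_mask=True), out_dir / pid)
    return ds
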