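"""Synthetic paired pre/postoperative macular OCT phantoms.

Real macular-hole cohorts are protected patient data, so every downstream
stage (registration, preprocessing, model training, agreement metrics) is
exercised on layered retinal phantoms with known ground truth.  A phantom
renders ten axial bands — nerve fiber, ganglion cell, inner plexiform, inner
nuclear, outer plexiform, outer nuclear layers, external limiting membrane
(ELM), ellipsoid zone (EZ), retinal pigment epithelium (RPE) and choroidal
vasculature — over a gently curved RPE floor with a foveal pit.  The
preoperative member carries a full-thickness crater through the neurosensory
retina and a known rigid misalignment; the postoperative member has a closed
hole, optionally with residual ELM/EZ band defects.

What the phantoms deliberately lack: OCT speckle statistics (noise is
additive Gaussian), vascular shadowing, and any pathology beyond the
full-thickness macular hole itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from .registration import RigidTransform, apply_transform
from .volume_io import OCTVolume, VoxelGeometry

__all__ = [
    "LAYER_NAMES",
    "DEFAULT_LAYER_THICKNESSES_UM",
    "LAYER_INTENSITIES",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomCase",
    "make_phantom_case",
    "make_cohort",
    "make_cohort_specs",
]

#: the ten distinguishable bands, inner to outer
LAYER_NAMES = (
    "NFL", "GCL", "IPL", "INL", "OPL", "ONL", "ELM", "EZ", "RPE", "choroid",
)

#: default band thicknesses in um (inner to outer); the neurosensory stack
#: (NFL..RPE) sums to 280 um, a realistic parafoveal retinal thickness
DEFAULT_LAYER_THICKNESSES_UM = (15.0, 35.0, 30.0, 30.0, 25.0, 80.0, 10.0, 25.0, 30.0, 200.0)

#: fixed mean gray level per band, alternating bright/dark so each band is
#: visible against its neighbours; RPE is the brightest (registration landmark)
LAYER_INTENSITIES = (200, 80, 150, 60, 140, 40, 225, 195, 250, 120)

#: the EZ band renders with a dark myoid zone in its upper fraction and the
#: bright ellipsoid line below, so the ELM stays separable from the EZ
MYOID_FRACTION = 0.4
MYOID_LEVEL = 30

#: effective mean gray level of each band as rendered (EZ mixes myoid+line)
LAYER_EFFECTIVE_INTENSITIES = tuple(
    (MYOID_FRACTION * MYOID_LEVEL + (1 - MYOID_FRACTION) * LAYER_INTENSITIES[7])
    if name == "EZ"
    else LAYER_INTENSITIES[i]
    for i, name in enumerate(LAYER_NAMES)
)

#: layers removed by a full-thickness hole (everything above the RPE)
_NEUROSENSORY = slice(0, 8)
#: inner layers thinned by the foveal pit (NFL..OPL plus part of ONL)
_PIT_LAYERS = slice(0, 5)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic pre/post case; the seed fixes output."""

    n_slices: int = 256
    n_axial: int = 992
    n_lateral: int = 512
    scan_width_um: float = 6000.0
    axial_pitch_um: float = 2.6
    layer_thicknesses_um: tuple = DEFAULT_LAYER_THICKNESSES_UM
    fovea_slice: int | None = None  # default: grid centre
    fovea_col: int | None = None
    pit_depth_um: float = 110.0
    pit_width_um: float = 1200.0
    hole_diameter_um: float = 450.0
    elm_gap_um: float = 0.0
    ez_gap_um: float = 0.0
    misalignment: RigidTransform = field(default_factory=RigidTransform.identity)
    noise_sd: float = 8.0
    seed: int = 0

    @property
    def geometry(self) -> VoxelGeometry:
        return VoxelGeometry.default(
            self.n_slices, self.n_lateral, self.scan_width_um, self.axial_pitch_um
        )

    @property
    def resolved_fovea(self) -> tuple[int, int]:
        fs = self.fovea_slice if self.fovea_slice is not None else self.n_slices // 2
        fc = self.fovea_col if self.fovea_col is not None else self.n_lateral // 2
        return fs, fc

    def validate(self) -> None:
        if self.hole_diameter_um < 0:
            raise ValueError("hole_diameter_um must be >= 0")
        if len(self.layer_thicknesses_um) != len(LAYER_NAMES):
            raise ValueError(f"need {len(LAYER_NAMES)} layer thicknesses")
        # the RPE floor bowls up to 40 um deeper towards the periphery
        depth_px = _base_depth_px(self) + (sum(self.layer_thicknesses_um) + 40.0) / self.axial_pitch_um
        if depth_px >= self.n_axial:
            raise ValueError(
                "geometry overflow: layer stack exceeds the axial extent "
                f"({depth_px:.0f} px needed, {self.n_axial} available)"
            )

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["misalignment"] = {
            "rotation": self.misalignment.rotation.tolist(),
            "translation": self.misalignment.translation.tolist(),
        }
        return d


@dataclass
class PhantomTruth:
    """Ground truth for one case, in the postoperative (fixed) frame.

    Surfaces are axial heights in fractional pixels on the (slice, column)
    grid; ``band_boundaries_px`` stacks the eleven band interfaces (vitreous/
    NFL down to the choroid floor) of the postoperative volume.
    """

    ilm_surface: np.ndarray
    rpe_surface: np.ndarray
    band_boundaries_px: np.ndarray
    fovea_slice: int
    fovea_col: int
    elm_status: str
    ez_status: str
    misalignment: RigidTransform

    def __post_init__(self) -> None:
        if not np.all(self.rpe_surface > self.ilm_surface):
            raise ValueError("RPE surface must lie strictly below the ILM")
        if self.elm_status not in ("restored", "disrupted"):
            raise ValueError("elm_status must be restored|disrupted")
        if self.ez_status not in ("restored", "disrupted"):
            raise ValueError("ez_status must be restored|disrupted")

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "fovea_slice": self.fovea_slice,
            "fovea_col": self.fovea_col,
            "elm_status": self.elm_status,
            "ez_status": self.ez_status,
            "ilm_surface": self.ilm_surface.tolist(),
            "rpe_surface": self.rpe_surface.tolist(),
            "misalignment": {
                "rotation": self.misalignment.rotation.tolist(),
                "translation": self.misalignment.translation.tolist(),
            },
        }
        path.write_text(json.dumps(payload))
        return path


@dataclass
class PhantomCase:
    case_id: str
    spec: PhantomSpec
    pre: OCTVolume
    post: OCTVolume
    truth: PhantomTruth


def _base_depth_px(spec: PhantomSpec) -> float:
    """Depth (pixels) of the ILM at the grid centre, placing the retina in
    the upper-middle of the axial window with room for misalignment."""
    return 0.30 * spec.n_axial


def _radial_um(spec: PhantomSpec, margin_slices: int = 0, margin_cols: int = 0) -> np.ndarray:
    """Distance of each (slice, column) from the fovea centre, in um.

    Margins extend the grid symmetrically beyond the nominal field (used
    when a misaligned volume must be rendered without border clipping).
    """
    fs, fc = spec.resolved_fovea
    g = spec.geometry
    ss, cc = np.meshgrid(
        np.arange(-margin_slices, spec.n_slices + margin_slices),
        np.arange(-margin_cols, spec.n_lateral + margin_cols),
        indexing="ij",
    )
    dy = (ss - fs) * g.slice_pitch
    dx = (cc - fc) * g.lateral_pitch
    return np.hypot(dy, dx)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _band_boundaries(
    spec: PhantomSpec,
    preoperative: bool,
    margin_slices: int = 0,
    margin_cols: int = 0,
) -> np.ndarray:
    """Eleven interface depth maps (pixels), index 0 = ILM, 10 = choroid floor."""
    r = _radial_um(spec, margin_slices, margin_cols)
    th = np.array(spec.layer_thicknesses_um, dtype=float)

    # per-point thickness of every band, (10, S, L)
    thick = np.broadcast_to(th[:, None, None], (len(th),) + r.shape).copy()

    # foveal pit: thin the inner layers towards zero at the centre
    sigma = spec.pit_width_um / 2.355  # width parameter from FWHM
    inner_total = th[_PIT_LAYERS].sum()
    pit = np.exp(-0.5 * (r / max(sigma, 1.0)) ** 2)
    pit_frac = min(spec.pit_depth_um / max(inner_total, 1.0), 0.95)
    thick[_PIT_LAYERS] *= 1.0 - pit_frac * pit[None]

    if preoperative and spec.hole_diameter_um > 0:
        # full-thickness crater: neurosensory bands vanish inside the hole
        # radius and recover smoothly over a 100 um rim
        radius = spec.hole_diameter_um / 2.0
        rim = 100.0
        f = _smoothstep((r - radius) / rim)
        thick[_NEUROSENSORY] *= f[None]

    # mild dome curvature of the RPE floor (deeper towards the periphery)
    bowl_um = 40.0 * (r / (spec.scan_width_um / 2.0)) ** 2
    rpe_top_um = _base_depth_px(spec) * spec.axial_pitch_um + th[:8].sum() + bowl_um

    bounds = np.empty((len(th) + 1,) + r.shape, dtype=float)
    # anchor at the RPE top so the landmark surface is unaffected by the
    # hole/pit shaping of the inner layers
    bounds[8] = rpe_top_um / spec.axial_pitch_um
    for k in range(7, -1, -1):
        bounds[k] = bounds[k + 1] - thick[k] / spec.axial_pitch_um
    for k in range(8, len(th)):
        bounds[k + 1] = bounds[k] + thick[k] / spec.axial_pitch_um
    return bounds


def _render(
    spec: PhantomSpec,
    bounds: np.ndarray,
    rng: np.random.Generator,
    band_defects: dict[int, float] | None = None,
    margins: tuple[int, int, int] = (0, 0, 0),
) -> np.ndarray:
    """Rasterise band interfaces into an 8-bit volume.

    ``band_defects`` maps a layer index to a lateral defect diameter (um):
    inside that radius of the fovea the band renders at the dark outer
    nuclear intensity instead of its own, emulating a focal discontinuity.
    ``margins`` symmetrically extend the rendered grid (slices, axial rows,
    columns); ``bounds`` must already be expressed on the extended grid.
    """
    ms, ma, ml = margins
    n_s, n_a, n_l = spec.n_slices + 2 * ms, spec.n_axial + 2 * ma, spec.n_lateral + 2 * ml
    z = np.arange(-ma, spec.n_axial + ma, dtype=np.float32)[None, :, None]
    r = _radial_um(spec, ms, ml)
    onl_level = LAYER_INTENSITIES[LAYER_NAMES.index("ONL")]
    ez_idx = LAYER_NAMES.index("EZ")
    b32 = bounds.astype(np.float32)
    split = b32[ez_idx] + MYOID_FRACTION * (b32[ez_idx + 1] - b32[ez_idx])
    lut = np.zeros(bounds.shape[0] + 1, dtype=np.float32)
    lut[1 : 1 + len(LAYER_INTENSITIES)] = LAYER_INTENSITIES

    out = np.empty((n_s, n_a, n_l), dtype=np.uint8)
    block = max(1, min(n_s, int(4e7 // (n_a * n_l)) or 1))
    for s0 in range(0, n_s, block):
        s1 = min(s0 + block, n_s)
        # band index per voxel: count of boundaries at or above each row, so
        # 0 = vitreous, k+1 = inside band k, n_bands+1 = below the stack
        count = np.zeros((s1 - s0, n_a, n_l), dtype=np.uint8)
        for k in range(bounds.shape[0]):
            count += z >= b32[k, s0:s1][:, None, :]
        img = lut[count]
        # dark myoid zone above the bright ellipsoid line within the EZ band
        myoid = z < split[s0:s1][:, None, :]
        img[(count == ez_idx + 1) & myoid] = MYOID_LEVEL
        if band_defects:
            for k, diameter in band_defects.items():
                if diameter <= 0:
                    continue
                gap = (r[s0:s1] <= diameter / 2.0)[:, None, :]
                sel = (count == k + 1) & gap
                if k == ez_idx:
                    sel &= ~myoid  # keep the myoid zone dark
                img[sel] = onl_level
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
        np.clip(np.rint(img), 0, 255, out=img)
        out[s0:s1] = img.astype(np.uint8)
    return out


def _margins_for(spec: PhantomSpec, t: RigidTransform) -> tuple[int, int, int]:
    """Per-axis rendering margins (slices, rows, cols) covering the largest
    displacement the rigid transform can produce anywhere in the field."""
    g = spec.geometry
    half_extent = 0.5 * np.array(
        [
            spec.n_slices * g.slice_pitch,
            spec.n_axial * spec.axial_pitch_um,
            spec.n_lateral * g.lateral_pitch,
        ]
    )
    radius = float(np.linalg.norm(half_extent))
    swing = 2.0 * np.sin(np.radians(t.rotation_angle_deg()) / 2.0) * radius
    disp = np.abs(t.translation) + swing
    pitches = np.array([g.slice_pitch, spec.axial_pitch_um, g.lateral_pitch])
    return tuple(int(np.ceil(d / p)) + 2 for d, p in zip(disp, pitches))


def make_phantom_case(spec: PhantomSpec, case_id: str = "case") -> PhantomCase:
    """Generate one paired pre/postoperative phantom with ground truth.

    The postoperative volume has a closed hole (with ELM/EZ gaps when the
    spec requests them); the preoperative volume contains the crater and is
    resampled through ``spec.misalignment``.  Identical specs (including
    seed) give byte-identical volumes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    geometry = spec.geometry
    fs, fc = spec.resolved_fovea

    post_bounds = _band_boundaries(spec, preoperative=False)

    defects = {}
    if spec.elm_gap_um > 0:
        defects[LAYER_NAMES.index("ELM")] = spec.elm_gap_um
    if spec.ez_gap_um > 0:
        defects[LAYER_NAMES.index("EZ")] = spec.ez_gap_um

    post_data = _render(spec, post_bounds, np.random.default_rng(spec.seed + 1), defects)
    post = OCTVolume(post_data, geometry)

    if spec.misalignment.is_identity():
        pre_bounds = _band_boundaries(spec, preoperative=True)
        pre = OCTVolume(_render(spec, pre_bounds, np.random.default_rng(spec.seed + 2)), geometry)
    else:
        # render on a grid extended past the nominal field so the rigid
        # resampling never pulls in clipped (zero-filled) borders — the
        # misaligned acquisition sees real tissue everywhere
        ms, ma, ml = _margins_for(spec, spec.misalignment)
        pre_bounds = _band_boundaries(spec, preoperative=True, margin_slices=ms, margin_cols=ml)
        ext = _render(
            spec, pre_bounds, np.random.default_rng(spec.seed + 2), margins=(ms, ma, ml)
        )
        moved = apply_transform(OCTVolume(ext, geometry), spec.misalignment)
        pre = OCTVolume(
            moved.data[
                ms : ms + spec.n_slices,
                ma : ma + spec.n_axial,
                ml : ml + spec.n_lateral,
            ].copy(),
            geometry,
        )

    rpe_idx = LAYER_NAMES.index("RPE")
    truth = PhantomTruth(
        ilm_surface=post_bounds[0].copy(),
        rpe_surface=(post_bounds[rpe_idx] + post_bounds[rpe_idx + 1]) / 2.0,
        band_boundaries_px=post_bounds,
        fovea_slice=fs,
        fovea_col=fc,
        elm_status="disrupted" if spec.elm_gap_um > 0 else "restored",
        ez_status="disrupted" if spec.ez_gap_um > 0 else "restored",
        misalignment=spec.misalignment,
    )
    return PhantomCase(case_id=case_id, spec=spec, pre=pre, post=post, truth=truth)


def make_cohort_specs(
    n_cases: int,
    base_spec: PhantomSpec,
    seed: int = 0,
    max_rot_deg: float = 3.0,
    max_shift_um: float = 80.0,
) -> list[PhantomSpec]:
    """Sample per-case specs around a base: hole size, thickness jitter,
    pit shape, ELM/EZ defects and rigid misalignment all vary.

    Hole diameters are drawn to emulate a surgical cohort (mean ~450 um,
    sd ~215 um, truncated at 100 um); roughly a quarter of cases keep a
    residual ELM defect and a third an EZ defect, matching the prevalence
    of incomplete outer-band recovery after surgery.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_cases):
        hole = float(np.clip(rng.normal(450.0, 215.0), 100.0, 1200.0))
        scale = rng.uniform(0.9, 1.1)
        thick = tuple(float(t * scale) for t in base_spec.layer_thicknesses_um)
        angles = rng.uniform(-max_rot_deg, max_rot_deg, size=3)
        shifts = rng.uniform(-max_shift_um, max_shift_um, size=3)
        elm_gap = float(rng.uniform(150.0, 500.0)) if rng.random() < 0.27 else 0.0
        ez_gap = float(rng.uniform(150.0, 500.0)) if rng.random() < 0.33 else 0.0
        specs.append(
            replace(
                base_spec,
                hole_diameter_um=hole,
                layer_thicknesses_um=thick,
                pit_depth_um=float(base_spec.pit_depth_um * rng.uniform(0.8, 1.2)),
                elm_gap_um=elm_gap,
                ez_gap_um=ez_gap,
                misalignment=RigidTransform.from_euler_deg(tuple(angles), tuple(shifts)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def make_cohort(
    n_cases: int,
    base_spec: PhantomSpec,
    seed: int = 0,
    **spec_kwargs,
) -> list[PhantomCase]:
    """Render a cohort of phantom cases; reproducible under the seed."""
    specs = make_cohort_specs(n_cases, base_spec, seed, **spec_kwargs)
    return [
        make_phantom_case(s, case_id=f"case{i:04d}") for i, s in enumerate(specs)
    ]
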