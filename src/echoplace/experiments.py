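"""Pre-packaged synthetic ensonification experiments.

Two study designs are mirrored end to end:

* a *spots* design — isolated device positions, each in its own habitat scene
  drawn from three archetypes (open: no reflectors in sonar range;
  semi-cluttered and cluttered: homogeneous Poisson point clutter at low and
  high density), analysed for per-direction classifiability and angular
  catchment;
* a *transect* design — device positions along a straight corridor line, in
  either a "boulder corridor" (sparse, strong, distant reflectors) or a
  "vegetation corridor" (dense, weak, near reflectors), analysed for linear
  catchment distances and the classifiability/continuity trade-off.

Full-scale configurations reproduce the study geometry (31 mics, 31×7 grid,
12 / 50 / 40 positions); smoke configurations shrink the microphone count,
grid and position count so a complete experiment runs in seconds to minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catchment import (
    CatchmentProfile,
    CatchmentSummary,
    TradeoffReport,
    angular_catchment,
    linear_catchment_summary,
    tradeoff_report,
)
from .classification import (
    ClassificationResult,
    NoiseModel,
    apply_floor_set,
    calibrate_sigma,
    classify_all,
    estimate_noise_floor,
)
from .scene import (
    ConfigurationError,
    DeviceSpec,
    DirectionGrid,
    Reflector,
    SamplingDesign,
    Scene,
    generate_scene,
)
from .templates import Template, TemplateSet, build_template_set

logger = logging.getLogger(__name__)

#: Poisson clutter densities per habitat archetype, reflectors / m³
ARCHETYPE_DENSITY = {"open": 0.0, "semi-cluttered": 0.08, "cluttered": 0.5}
#: habitat bounding box around a device pose, metres
HABITAT_REGION = ((-6.0, 6.0), (-6.0, 6.0), (-3.0, 3.0))


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Fully serializable description of one synthetic experiment."""

    name: str
    spec: DeviceSpec
    design: SamplingDesign
    scenes: list[Scene]
    seed: int
    jnd_db: float = 2.0
    criterion: float = 0.75
    calibration_range: float = 2.0  # m, range of the JND reference echo
    habitat_labels: list[str] | None = None


def spots_config(
    seed: int,
    archetypes: Sequence[str] = ("open",) * 4 + ("semi-cluttered",) * 4 + ("cluttered",) * 4,
    spec: DeviceSpec | None = None,
    strength: float = 1.0,
    strength_spread: float = 0.3,
) -> ExperimentConfig:
    """Spot-design study: one independent habitat scene per device position.

    The default archetype list mirrors the 12-position design (4 open, 4
    semi-cluttered, 4 cluttered); pass a shorter list for a smoke run.
    """
    spec = spec or DeviceSpec()
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5B07])
    seeds = ss.generate_state(len(archetypes))
    scenes = [
        generate_scene(
            a,
            ARCHETYPE_DENSITY[a],
            HABITAT_REGION,
            int(s & 0x7FFFFFFF),
            strength=strength,
            strength_spread=strength_spread,
        )
        for a, s in zip(archetypes, seeds)
    ]
    design = SamplingDesign(
        poses=np.zeros((len(archetypes), 3)), design_name="spots"
    )
    return ExperimentConfig(
        name="spots",
        spec=spec,
        design=design,
        scenes=scenes,
        seed=seed,
        habitat_labels=list(archetypes),
    )


def make_corridor_scene(
    kind: str,
    length: float,
    seed: int,
    wall_distance: float | None = None,
    strength: float | None = None,
) -> Scene:
    """Corridor scene flanking a transect along the +x axis.

    ``kind='boulder'``: a continuous rough rock wall 5.2 m from the line —
    strong reflectors (Poisson-placed along-track at ~3/m, lognormal
    strengths around 5) piled from ground level up to ~2 m, the
    strong-distant-reflector archetype.  ``kind='vegetation'``: dense weak
    foliage elements (strengths around 0.2) along walls only 0.9 m from the
    line with ~1.5 m of vertical extent, the weak-near-reflector archetype.
    Both walls have vertical structure so that off-horizon gaze directions
    still receive echoes.
    """
    rng = np.random.default_rng(seed)
    reflectors: list[Reflector] = []
    if kind == "boulder":
        wall = 5.2 if wall_distance is None else wall_distance
        s = 5.0 if strength is None else strength
        for side in (-wall, wall):
            n = rng.poisson(3.0 * (length + 6.0))
            xs = rng.uniform(-3.0, length + 3.0, n)
            for x in xs:
                p = np.array([x, side, 0.0]) + np.array(
                    [rng.normal(0, 0.25), rng.normal(0, 0.25), rng.uniform(-0.5, 2.0)]
                )
                reflectors.append(
                    Reflector(p, s * np.exp(rng.normal(0, 0.3)), kind="boulder")
                )
    elif kind == "vegetation":
        wall = 0.9 if wall_distance is None else wall_distance
        s = 0.2 if strength is None else strength
        for side in (-wall, wall):
            for x in np.arange(-2.0, length + 2.0, 0.2):
                for _ in range(3):
                    p = np.array([x, side, 0.0]) + np.array(
                        [rng.normal(0, 0.4), rng.normal(0, 0.4), rng.uniform(-0.6, 1.5)]
                    )
                    reflectors.append(
                        Reflector(p, s * np.exp(rng.normal(0, 0.3)), kind="foliage-element")
                    )
    else:
        raise ConfigurationError(f"unknown corridor kind {kind!r}")
    return Scene(tuple(reflectors), archetype=kind, rng_seed=seed)


def transect_config(
    seed: int,
    kind: str,
    n_positions: int = 50,
    spacing: float = 0.20,
    spec: DeviceSpec | None = None,
) -> ExperimentConfig:
    """Transect study along a corridor.  Full-scale defaults mirror the
    50-position × 20 cm design; the 40-position × 25 cm variant and smoke
    runs are parameter changes."""
    spec = spec or DeviceSpec()
    design = SamplingDesign.transect(n_positions, spacing)
    length = (n_positions - 1) * spacing
    scene = make_corridor_scene(kind, length, int(seed) & 0x7FFFFFFF)
    return ExperimentConfig(
        name=f"transect-{kind}",
        spec=spec,
        design=design,
        scenes=[scene] * n_positions,
        seed=seed,
        habitat_labels=[kind] * n_positions,
    )


def smoke_spec(n_mics: int = 2, n_az: int = 31, n_el: int = 7) -> DeviceSpec:
    """Reduced device for fast experiments: fewer microphones and, optionally,
    a coarser gaze grid spanning the same field of view."""
    grid = (
        DirectionGrid.default()
        if (n_az, n_el) == (31, 7)
        else DirectionGrid.reduced(n_az, n_el)
    )
    return DeviceSpec(n_mics=n_mics, grid=grid)


# ---------------------------------------------------------------------------
# noise-model construction
# ---------------------------------------------------------------------------


def reflector_free_templates(spec: DeviceSpec, seed: int) -> list[Template]:
    """Templates from device-noise-only recordings (no reflectors in range),
    used to estimate the noise floor n_f."""
    scene = Scene((), archetype="open", rng_seed=seed)
    design = SamplingDesign(poses=np.zeros((1, 3)))
    tset = build_template_set(scene, design, spec, rng_seed=seed)
    return tset.templates


def calibration_pair(
    spec: DeviceSpec, jnd_db: float = 2.0, range_m: float = 2.0, strength: float = 1.0
) -> tuple[Template, Template]:
    """Single-echo reference template and its JND sibling.

    A lone point reflector sits on boresight at ``range_m``; synthesis is
    noiseless and runs through the full template pipeline on a 3×3 gaze grid
    centred on boresight (so the centre direction receives the complete 3×3
    spatial average).  The sibling's echo waveform is scaled by
    10^(jnd_db/20).
    """
    grid = DirectionGrid(
        azimuths=np.array([-10.0, 0.0, 10.0]),
        elevations=np.array([-10.8, 0.0, 10.8]),
    )
    cal_spec = spec.with_(grid=grid, self_noise_level=0.0)
    design = SamplingDesign(poses=np.zeros((1, 3)))
    centre = grid.index_of(1, 1)
    out = []
    for s in (strength, strength * 10 ** (jnd_db / 20.0)):
        scene = Scene((Reflector((range_m, 0.0, 0.0), s),), archetype="open")
        tset = build_template_set(scene, design, cal_spec, rng_seed=0)
        out.append(tset.templates[centre])
    return out[0], out[1]


def build_noise_model(
    spec: DeviceSpec,
    seed: int,
    jnd_db: float = 2.0,
    criterion: float = 0.75,
    calibration_range: float = 2.0,
    mc_check_draws: int = 0,
) -> NoiseModel:
    """Estimate n_f from reflector-free recordings, then calibrate σ_n² on
    the floored JND template pair."""
    n_f = estimate_noise_floor(reflector_free_templates(spec, seed))
    ref, sib = calibration_pair(spec, jnd_db=jnd_db, range_m=calibration_range)
    ref_f = Template(np.maximum(ref.values, n_f))
    sib_f = Template(np.maximum(sib.values, n_f))
    sigma_n2 = calibrate_sigma(
        ref_f, sib_f, criterion=criterion, mc_draws=mc_check_draws, seed=seed
    )
    return NoiseModel(n_f=n_f, sigma_n2=sigma_n2, jnd_db=jnd_db, criterion=criterion)


# ---------------------------------------------------------------------------
# experiment runners
# ---------------------------------------------------------------------------


@dataclass
class SpotsResult:
    config: ExperimentConfig
    template_set: TemplateSet
    noise: NoiseModel
    per_position: list[ClassificationResult]
    angular_profiles: list[CatchmentProfile]

    def pc_by_habitat(self) -> dict[str, np.ndarray]:
        out: dict[str, list] = {}
        for label, res in zip(self.config.habitat_labels, self.per_position):
            out.setdefault(label, []).append(res.pc)
        return {k: np.concatenate(v) for k, v in out.items()}


def run_spots_experiment(
    config: ExperimentConfig, noise: NoiseModel | None = None
) -> SpotsResult:
    """Full spots pipeline: templates, noise model, per-position
    classification (each position classified against its own panorama) and
    per-position angular catchment profiles."""
    spec = config.spec
    tset = build_template_set(config.scenes, config.design, spec, rng_seed=config.seed)
    if noise is None:
        noise = build_noise_model(
            spec, config.seed, config.jnd_db, config.criterion, config.calibration_range
        )
    floored = apply_floor_set(tset, noise.n_f)
    per_position: list[ClassificationResult] = []
    profiles: list[CatchmentProfile] = []
    for p in range(config.design.n_positions):
        sub = floored.subset(floored.position_indices == p)
        per_position.append(classify_all(sub, noise, seed=config.seed + p))
        profiles.append(angular_catchment(floored, p, noise.sigma_n2))
    return SpotsResult(config, floored, noise, per_position, profiles)


@dataclass
class TransectResult:
    config: ExperimentConfig
    template_set: TemplateSet
    noise: NoiseModel
    classification: ClassificationResult
    catchment: CatchmentSummary
    catchment_per_position: np.ndarray  # (n_directions, n_positions), metres
    tradeoff: TradeoffReport

    @property
    def mean_pc(self) -> float:
        return float(self.classification.pc.mean())

    @property
    def median_catchment(self) -> float:
        return float(np.median(self.catchment_per_position))

    def matched_pc_catchment(self) -> tuple[np.ndarray, np.ndarray]:
        """P_c and linear catchment paired per (position, direction) template."""
        tset = self.template_set
        d_indices = np.unique(tset.direction_indices)
        p_indices = np.unique(tset.position_indices)
        pc = np.zeros(len(d_indices) * len(p_indices))
        catch = np.zeros_like(pc)
        lut = {
            (t.position_index, t.direction_index): k
            for k, t in enumerate(tset.templates)
        }
        k = 0
        for j, d in enumerate(d_indices):
            for xi, p in enumerate(np.sort(p_indices)):
                pc[k] = self.classification.pc[lut[(p, d)]]
                catch[k] = self.catchment_per_position[j, xi]
                k += 1
        return pc, catch


def run_transect_experiment(
    config: ExperimentConfig, noise: NoiseModel | None = None
) -> TransectResult:
    """Full transect pipeline: templates, classification against the whole
    transect pool, per-direction linear catchments and the per-template
    trade-off statistics."""
    spec = config.spec
    tset = build_template_set(
        config.scenes[0], config.design, spec, rng_seed=config.seed
    )
    if noise is None:
        noise = build_noise_model(
            spec, config.seed, config.jnd_db, config.criterion, config.calibration_range
        )
    floored = apply_floor_set(tset, noise.n_f)
    cls = classify_all(floored, noise, seed=config.seed)
    summary, per_pos = linear_catchment_summary(floored, noise.sigma_n2)
    res = TransectResult(
        config, floored, noise, cls, summary, per_pos, tradeoff_report([0], [0])
    )
    pc, catch = res.matched_pc_catchment()
    res.tradeoff = tradeoff_report(pc, catch)
    return res


def run_corridor_pair(
    seed: int,
    n_positions: int = 16,
    spacing: float = 0.25,
    spec: DeviceSpec | None = None,
    noise: NoiseModel | None = None,
) -> dict:
    """Matched-seed boulder vs vegetation corridor comparison.

    Returns the per-site median linear catchment and mean P_c, the pooled
    Spearman correlation between P_c and catchment, and the two-site rank-sum
    statistic on the catchments.
    """
    spec = spec or smoke_spec(n_mics=2, n_az=11, n_el=3)
    results = {}
    pooled_pc, pooled_catch, labels = [], [], []
    for kind in ("boulder", "vegetation"):
        cfg = transect_config(seed, kind, n_positions, spacing, spec=spec)
        res = run_transect_experiment(cfg, noise=noise)
        results[kind] = res
        pc, catch = res.matched_pc_catchment()
        pooled_pc.append(pc)
        pooled_catch.append(catch)
        labels.append(np.full(len(pc), kind, dtype=object))
    pooled = tradeoff_report(
        np.concatenate(pooled_pc), np.concatenate(pooled_catch), np.concatenate(labels)
    )
    return {
        "boulder": results["boulder"],
        "vegetation": results["vegetation"],
        "median_catchment": {
            k: results[k].median_catchment for k in ("boulder", "vegetation")
        },
        "mean_pc": {k: results[k].mean_pc for k in ("boulder", "vegetation")},
        "pooled_tradeoff": pooled,
    }


def full_study_counts(spec: DeviceSpec | None = None) -> dict:
    """Exact echo-train and template count contracts of the full study design
    (12 spots + 50-position and 40-position transects)."""
    spec = spec or DeviceSpec()
    spots = SamplingDesign(poses=np.zeros((12, 3)))
    t50 = SamplingDesign.transect(50, 0.20)
    t40 = SamplingDesign.transect(40, 0.25)
    per_mic = {
        "spots": spots.n_echo_trains(spec, per_mic=True),
        "transect_50": t50.n_echo_trains(spec, per_mic=True),
        "transect_40": t40.n_echo_trains(spec, per_mic=True),
    }
    per_mic["total"] = sum(per_mic.values())
    total = sum(
        d.n_echo_trains(spec) for d in (spots, t50, t40)
    )
    n_positions = spots.n_positions + t50.n_positions + t40.n_positions
    return {
        "per_mic": per_mic,
        "total_echo_trains": total,
        "n_templates": n_positions * spec.grid.n_directions,
    }
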