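"""Seeded synthetic behavioral-screen generator.

Emulates the statistical structure of a high-replicate larval-zebrafish
96-well screen: each pseudo-drug belongs to one of a small number of
phenotype classes, each class has a stimulus-locked motion-index response
template (startle bursts to acoustic/tap stimuli, sustained shifts under
light epochs), replicates get time/amplitude jitter plus additive and
high-frequency sensor noise, plates carry vehicle (DMSO/H2O, treated
identically) and lethal (eugenol) control wells, a configurable fraction of
drugs is behaviorally inactive (vehicle-identical template), and an
optional deterministic well-position-keyed near-Nyquist artifact can be
planted to reproduce shortcut-learning conditions.

Plate layouts are either ``fixed`` (every replicate of a drug at the same
well across plates — the naive screen design) or ``randomized`` (seeded
uniform permutation of drugs over treatment positions per plate — the
revised design).  Control positions stay canonical in both modes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (ROLE_DRUG, ROLE_LETHAL, ROLE_VEHICLE, ScreenDataset,
                 format_well_name)

__all__ = [
    "StimulusSchedule",
    "SimConfig",
    "SyntheticGroundTruth",
    "default_stimulus_schedule",
    "generate_layout",
    "generate_screen",
    "plant_positional_artifact",
    "write_ground_truth",
    "read_ground_truth",
]

STIMULUS_KINDS = ("dark", "blue_light", "purple_light", "acoustic", "tap")

#: Planted artifact frequency in cycles/frame — just below Nyquist (0.5),
#: so it aliases into stride-5 subsampled inputs but dies under Hanning(11).
ARTIFACT_FREQ = 0.45

PLATE_ROWS, PLATE_COLS = 8, 12
WELLS_PER_PLATE = PLATE_ROWS * PLATE_COLS


@dataclass
class StimulusSchedule:
    """Ordered, non-overlapping stimulus epochs covering the whole trace."""

    epochs: list[tuple[int, int, str]]
    frame_rate: float = 25.0

    def __post_init__(self):
        prev_end = 0
        for start, end, kind in self.epochs:
            if kind not in STIMULUS_KINDS:
                raise ValueError(f"unknown stimulus kind {kind!r}")
            if end <= start:
                raise ValueError(f"epoch ({start}, {end}) has end <= start")
            if start != prev_end:
                raise ValueError("epochs must tile the trace without gaps/overlap")
            prev_end = end
        if not self.epochs or self.epochs[0][0] != 0:
            raise ValueError("epochs must start at frame 0")

    @property
    def length(self) -> int:
        return self.epochs[-1][1]

    def to_dict(self) -> dict:
        return {"epochs": [list(e) for e in self.epochs], "frame_rate": self.frame_rate}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        return cls(epochs=[tuple(e) for e in d["epochs"]],
                   frame_rate=d.get("frame_rate", 25.0))


#: Canonical 10-epoch assay block pattern (roughly: habituation dark,
#: light epochs, acoustic/tap startle batteries, recovery dark).
_EPOCH_PATTERN = ("dark", "blue_light", "dark", "acoustic", "purple_light",
                  "dark", "tap", "blue_light", "dark", "tap")


def default_stimulus_schedule(trace_length: int, frame_rate: float = 25.0) -> StimulusSchedule:
    n = len(_EPOCH_PATTERN)
    bounds = np.linspace(0, trace_length, n + 1).astype(int)
    epochs = [(int(bounds[i]), int(bounds[i + 1]), _EPOCH_PATTERN[i]) for i in range(n)]
    return StimulusSchedule(epochs=epochs, frame_rate=frame_rate)


@dataclass
class SimConfig:
    """Synthetic screen parameters.

    Defaults mirror the screening design this simulator emulates: 96-well
    plates, 7–10 replicates per drug, 8+2 vehicle and 2 lethal control wells
    per plate, a quarter of drugs behaviorally inactive.  ``trace_length``
    defaults to a reduced 5,000 frames for desk-scale runs; the canonical
    101,250-frame length is supported.
    """

    n_plates: int = 10
    n_drugs: int = 24
    replicates_per_drug: tuple[int, int] = (7, 10)
    n_phenotype_classes: int = 8
    inactive_fraction: float = 0.25
    trace_length: int = 5000
    layout_mode: str = "randomized"
    artifact_amplitude: float = 0.0
    noise_scale: float = 25.0
    sensor_noise_scale: float = 12.0
    time_jitter_sd: float = 35.0        # frames (~1.4 s): per-response latency spread
    amplitude_jitter_sd: float = 0.25   # log-scale well-to-well response amplitude
    response_reliability: float = 0.9   # per-stimulus probability the well responds
    epoch_amplitude_jitter_sd: float = 0.3  # log-scale per-stimulus response gain
    transition_spike_amplitude: float = 400.0  # imaging spike at light transitions
    controls_per_plate: tuple[int, int] = (10, 2)  # (vehicle = 8 DMSO + 2 H2O, lethal)
    n_targets: int = 32
    #: seed for the class response templates only; None -> use ``seed``.
    #: Two screens with equal template_seed share phenotype classes while
    #: differing in drugs, layout and noise (a query vs. library pairing).
    template_seed: int | None = None
    class_separation: float = 1.0
    drug_within_class_spread: float = 0.45
    trace_max: float = 6750.0
    frame_rate: float = 25.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.replicates_per_drug
        if not (1 <= lo <= hi):
            raise ValueError(f"bad replicate range {self.replicates_per_drug}")
        if not (0.0 <= self.inactive_fraction <= 1.0):
            raise ValueError("inactive_fraction must be in [0, 1]")
        if self.layout_mode not in ("fixed", "randomized"):
            raise ValueError(f"layout_mode must be fixed|randomized, got {self.layout_mode!r}")
        if self.artifact_amplitude < 0 or self.noise_scale < 0:
            raise ValueError("artifact_amplitude and noise_scale must be >= 0")
        n_controls = sum(self.controls_per_plate)
        n_treat = WELLS_PER_PLATE - n_controls
        if self.n_drugs + n_controls > WELLS_PER_PLATE:
            raise ValueError(
                f"capacity exceeded: {self.n_drugs} drugs + {n_controls} controls "
                f"= {self.n_drugs + n_controls} wells > {WELLS_PER_PLATE} on a plate "
                f"(deficit {self.n_drugs + n_controls - WELLS_PER_PLATE})")
        if hi > self.n_plates:
            raise ValueError(
                f"capacity exceeded: up to {hi} replicates requested but only "
                f"{self.n_plates} plates (deficit {hi - self.n_plates})")
        if self.n_drugs * hi > n_treat * self.n_plates:
            raise ValueError(
                f"capacity exceeded: {self.n_drugs} drugs x {hi} replicates "
                f"> {n_treat * self.n_plates} treatment wells")


@dataclass
class SyntheticGroundTruth:
    """What the simulator knows and analysis code must rediscover."""

    class_of_drug: dict[str, int]
    active: dict[str, bool]
    target_profile: dict[str, np.ndarray]
    artifact_field: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "class_of_drug": self.class_of_drug,
            "active": self.active,
            "target_profile": {k: np.asarray(v).astype(int).tolist()
                               for k, v in self.target_profile.items()},
            "artifact_field": self.artifact_field,
        }


def write_ground_truth(gt: SyntheticGroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(gt.to_jsonable(), indent=1))
    return path


def read_ground_truth(path: str | Path) -> SyntheticGroundTruth:
    d = json.loads(Path(path).read_text())
    return SyntheticGroundTruth(
        class_of_drug={k: int(v) for k, v in d["class_of_drug"].items()},
        active={k: bool(v) for k, v in d["active"].items()},
        target_profile={k: np.asarray(v, dtype=np.int8)
                        for k, v in d["target_profile"].items()},
        artifact_field=d.get("artifact_field", {}),
    )


# ---------------------------------------------------------------------------
# Layout


def _control_positions(n_vehicle: int, n_lethal: int) -> tuple[list, list]:
    """Canonical control wells: edge columns first (0, 11, 1, 10, ...)."""
    col_order = []
    for k in range(PLATE_COLS // 2):
        col_order += [k, PLATE_COLS - 1 - k]
    slots = [(r, c) for c in col_order for r in range(PLATE_ROWS)]
    if n_vehicle + n_lethal > len(slots):
        raise ValueError(f"too many controls per plate ({n_vehicle + n_lethal} > {len(slots)})")
    return slots[:n_vehicle], slots[n_vehicle:n_vehicle + n_lethal]


def _drug_id(i: int) -> str:
    return f"drug{i:04d}"


def _replicate_plan(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Seeded per-drug replicate counts and which plates carry each drug."""
    lo, hi = config.replicates_per_drug
    plan = {}
    for i in range(config.n_drugs):
        r = int(rng.integers(lo, hi + 1))
        plates = np.sort(rng.choice(config.n_plates, size=r, replace=False))
        plan[_drug_id(i)] = plates
    return plan


def generate_layout(config: SimConfig):
    """Emit one WellRecord per well of every plate (n_plates x 96 records).

    Treatment positions a drug does not occupy on a given plate are filled
    with extra vehicle wells so each plate is complete.
    """
    from .pair_builder import WellRecord

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n_vehicle, n_lethal = config.controls_per_plate
    vehicle_pos, lethal_pos = _control_positions(n_vehicle, n_lethal)
    control_set = set(vehicle_pos) | set(lethal_pos)
    treatment_pos = [(r, c) for r in range(PLATE_ROWS) for c in range(PLATE_COLS)
                     if (r, c) not in control_set]
    plan = _replicate_plan(config, rng)
    fixed_slot = {_drug_id(i): treatment_pos[i] for i in range(config.n_drugs)}
    rep_counter: dict[str, int] = {d: 0 for d in plan}

    records = []
    for plate in range(config.n_plates):
        plate_id = f"plate{plate:02d}"
        drugs_here = [d for d, plates in plan.items() if plate in plates]
        if config.layout_mode == "fixed":
            assignment = {fixed_slot[d]: d for d in drugs_here}
        else:
            shuffled = list(rng.permutation(len(treatment_pos)))
            assignment = {treatment_pos[shuffled[i]]: d for i, d in enumerate(drugs_here)}
        for r in range(PLATE_ROWS):
            for c in range(PLATE_COLS):
                pos = (r, c)
                if pos in assignment:
                    drug = assignment[pos]
                    treatment, role = drug, ROLE_DRUG
                    rep = rep_counter[drug]
                    rep_counter[drug] += 1
                elif pos in set(vehicle_pos):
                    idx = vehicle_pos.index(pos)
                    treatment = "DMSO" if idx < max(n_vehicle - 2, 0) else "H2O"
                    role, rep = ROLE_VEHICLE, plate
                elif pos in set(lethal_pos):
                    treatment, role, rep = "EUG", ROLE_LETHAL, plate
                else:
                    treatment, role, rep = "DMSO", ROLE_VEHICLE, plate
                records.append(WellRecord(
                    well_id=f"{plate_id}-{format_well_name(r, c)}",
                    plate_id=plate_id, row=r, col=c,
                    treatment_id=treatment, role=role, replicate_index=rep))
    return records


def _wells_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


# ---------------------------------------------------------------------------
# Response templates


def _vehicle_params() -> dict:
    """Canonical vehicle response: modest startles, mild light modulation."""
    return {"baseline": 250.0,
            "gain": {"blue_light": 1.0, "purple_light": 1.0, "acoustic": 1.0, "tap": 1.0},
            "latency": {"blue_light": 0, "purple_light": 0, "acoustic": 0, "tap": 0},
            "tau": 90.0}

#: Vehicle-level response amplitudes per stimulus kind (MI units).
_BASE_AMPLITUDE = {"blue_light": 350.0, "purple_light": 280.0,
                   "acoustic": 1200.0, "tap": 1500.0}


def _class_params(class_rng: np.random.Generator, separation: float) -> dict:
    """Class identity lives mostly in tonic (baseline) activity and startle
    gain/shape; sustained light responses differ more modestly — sedatives
    and stimulants shift overall locomotion more than they reshape acute
    photoresponses."""
    p = _vehicle_params()
    p["baseline"] *= float(max(0.1, 1.0 + 0.8 * separation * class_rng.uniform(-0.9, 0.9)))
    for kind in _BASE_AMPLITUDE:
        p["gain"][kind] = float(max(0.05, 1.0 + 0.5 * separation * class_rng.uniform(-0.9, 1.2)))
        p["latency"][kind] = int(round(abs(class_rng.normal(0.0, 25.0)) * separation))
    p["tau"] = float(90.0 * (1.0 + 0.6 * separation * class_rng.uniform(-0.8, 0.8)))
    return p


def _perturb_params(params: dict, rng: np.random.Generator, spread: float) -> dict:
    q = {"baseline": params["baseline"] * float(1.0 + spread * rng.uniform(-1, 1)),
         "gain": {}, "latency": {}, "tau": params["tau"] * float(1.0 + spread * rng.uniform(-1, 1))}
    for kind in params["gain"]:
        q["gain"][kind] = params["gain"][kind] * float(1.0 + spread * rng.uniform(-1, 1))
        q["latency"][kind] = int(params["latency"][kind] + round(rng.normal(0, 3)))
    return q


def render_template_components(schedule: StimulusSchedule,
                               params: dict) -> tuple[np.ndarray, list[np.ndarray]]:
    """(constant baseline trace, one response component per stimulus epoch).

    Components are full-length arrays so they can be gated, scaled and
    time-shifted independently per replicate before summing.
    """
    length = schedule.length
    t = np.arange(length, dtype=float)
    baseline = np.full(length, params["baseline"], dtype=float)
    components = []
    for start, end, kind in schedule.epochs:
        if kind == "dark":
            continue
        amp = _BASE_AMPLITUDE[kind] * params["gain"][kind]
        onset = start + max(params["latency"][kind], 0)
        if onset >= end:
            continue
        comp = np.zeros(length)
        seg = t[onset:end] - onset
        if kind in ("acoustic", "tap"):
            # sharp startle burst decaying with class time constant
            comp[onset:end] = amp * np.exp(-seg / max(params["tau"], 1.0))
        else:
            # sustained light response ramping over ~30 frames
            comp[onset:end] = amp * (1.0 - np.exp(-seg / 30.0))
        components.append((kind, comp))
    return baseline, components


def render_template(schedule: StimulusSchedule, params: dict) -> np.ndarray:
    """Deterministic expected response trace (baseline + all components)."""
    baseline, components = render_template_components(schedule, params)
    return baseline + np.sum([c for _, c in components], axis=0) if components else baseline


def _lethal_template(length: int) -> np.ndarray:
    return np.full(length, 3.0)


def _transition_spikes(schedule: StimulusSchedule, amplitude: float) -> np.ndarray:
    """Camera-level MI spikes at light-epoch transitions.

    A global illumination change flips pixel intensities across the whole
    frame, so the motion index spikes at light onsets/offsets in every well
    — including wells with motionless fish.
    """
    spikes = np.zeros(schedule.length)
    for start, end, kind in schedule.epochs:
        if kind in ("blue_light", "purple_light"):
            for edge in (start, end):
                if 0 < edge < schedule.length - 1:
                    spikes[edge] += amplitude
                    spikes[edge + 1] += 0.5 * amplitude
    return spikes


# ---------------------------------------------------------------------------
# Screen generation


def _replicate_trace(template: tuple[np.ndarray, list[np.ndarray]],
                     rng: np.random.Generator, config: SimConfig,
                     spikes: np.ndarray | None = None,
                     quiet: bool = False) -> np.ndarray:
    """One well's trace: gated/jittered response components + baseline + noise.

    Brief startle responses (acoustic/tap) fire with probability
    ``response_reliability`` and carry per-presentation latency jitter —
    fish startle probabilistically and with variable timing.  Sustained
    light responses and the baseline are replicate-stable apart from gain
    jitter.  A global log-normal amplitude scale models well-to-well
    differences (fish number/size).  ``quiet`` marks motionless
    (lethal-control) wells: no behavioral response and motion-driven noise
    shrunk to a residual 10%, since the MI of a still well barely crosses
    the pixel-change threshold.
    """
    baseline, components = template
    scale = float(np.exp(rng.normal(0.0, config.amplitude_jitter_sd)))
    trace = scale * baseline.copy()
    for kind, comp in components:
        fires = rng.random() < config.response_reliability
        gain = float(np.exp(rng.normal(0.0, config.epoch_amplitude_jitter_sd)))
        shift = int(round(rng.normal(0.0, config.time_jitter_sd)))
        if quiet:
            continue
        if kind in ("acoustic", "tap"):
            if fires:
                trace += scale * gain * np.roll(comp, shift)
        else:
            trace += scale * gain * comp
    noise_sd = config.noise_scale * (0.1 if quiet else 1.0)
    sensor_sd = config.sensor_noise_scale * (0.1 if quiet else 1.0)
    if spikes is not None:
        trace = trace + spikes
    trace = trace + rng.normal(0.0, noise_sd, size=trace.shape)
    white = rng.normal(0.0, sensor_sd, size=trace.shape)
    hf = np.empty_like(white)       # first-difference filter: flat-to-rising
    hf[0] = white[0]                # spectrum, power concentrated near Nyquist
    hf[1:] = (white[1:] - white[:-1]) / np.sqrt(2.0)
    trace = trace + hf
    return np.clip(trace, 0.0, config.trace_max)


def _make_ground_truth(config: SimConfig, rng: np.random.Generator) -> SyntheticGroundTruth:
    n_classes = config.n_phenotype_classes
    class_of = {_drug_id(i): i % n_classes for i in range(config.n_drugs)}
    n_inactive = int(round(config.inactive_fraction * config.n_drugs))
    inactive = set(rng.choice(config.n_drugs, size=n_inactive, replace=False).tolist())
    active = {_drug_id(i): (i not in inactive) for i in range(config.n_drugs)}
    profiles = {}
    for i in range(config.n_drugs):
        prof = np.zeros(config.n_targets, dtype=np.int8)
        if active[_drug_id(i)]:
            cls = class_of[_drug_id(i)]
            for j in range(3):      # class-shared targets
                prof[(3 * cls + j) % config.n_targets] = 1
        prof[int(rng.integers(config.n_targets))] = 1  # drug-specific target
        profiles[_drug_id(i)] = prof
    return SyntheticGroundTruth(class_of_drug=class_of, active=active,
                                target_profile=profiles)


def generate_screen(config: SimConfig) -> tuple[ScreenDataset, SyntheticGroundTruth]:
    """Simulate a full screen; bit-identical for identical configs."""
    records = generate_layout(config)
    wells = _wells_frame(records)
    schedule = default_stimulus_schedule(config.trace_length, config.frame_rate)
    gt_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    gt = _make_ground_truth(config, gt_rng)

    tseed = config.seed if config.template_seed is None else config.template_seed
    class_templates = {}
    for cls in range(config.n_phenotype_classes):
        crng = np.random.default_rng(np.random.SeedSequence([tseed, 3, cls]))
        class_templates[cls] = _class_params(crng, config.class_separation)
    vehicle = _vehicle_params()
    drug_params = {}
    for i in range(config.n_drugs):
        d = _drug_id(i)
        drng = np.random.default_rng(np.random.SeedSequence([config.seed, 4, i]))
        if gt.active[d]:
            drug_params[d] = _perturb_params(class_templates[gt.class_of_drug[d]],
                                             drng, config.drug_within_class_spread)
        else:
            # inactive drugs are behaviorally vehicle-identical
            drug_params[d] = vehicle

    rendered = {d: render_template_components(schedule, p)
                for d, p in drug_params.items()}
    vehicle_template = render_template_components(schedule, vehicle)
    lethal_template = (_lethal_template(config.trace_length), [])

    spikes = _transition_spikes(schedule, config.transition_spike_amplitude)
    trace_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    traces = np.empty((len(wells), config.trace_length), dtype=float)
    for idx, rec in enumerate(records):
        if rec.role == ROLE_LETHAL:
            base = lethal_template
        elif rec.role == ROLE_VEHICLE:
            base = vehicle_template
        else:
            base = rendered[rec.treatment_id]
        traces[idx] = _replicate_trace(base, trace_rng, config, spikes=spikes,
                                       quiet=rec.role == ROLE_LETHAL)

    dataset = ScreenDataset(
        traces=traces, wells=wells, schedule=schedule,
        provenance={"source": "phenotwin.synthetic_data", "seed": config.seed,
                    "layout_mode": config.layout_mode,
                    "artifact_amplitude": config.artifact_amplitude})
    if config.artifact_amplitude > 0:
        dataset = plant_positional_artifact(dataset, gt, config.artifact_amplitude)
    return dataset, gt


def _artifact_component(row: int, col: int, length: int, amplitude: float) -> np.ndarray:
    """Deterministic near-Nyquist component, smooth in plate coordinates."""
    amp = amplitude * (0.6 + 0.4 * (row / (PLATE_ROWS - 1) + col / (PLATE_COLS - 1)) / 2.0)
    phase = 2.0 * np.pi * (0.31 * row / (PLATE_ROWS - 1) + 0.63 * col / (PLATE_COLS - 1))
    t = np.arange(length, dtype=float)
    return amp * np.cos(2.0 * np.pi * ARTIFACT_FREQ * t + phase)


def plant_positional_artifact(dataset: ScreenDataset,
                              ground_truth: SyntheticGroundTruth | None = None,
                              amplitude: float = 0.0) -> ScreenDataset:
    """Add a well-position-keyed high-frequency component to every trace.

    The component depends only on (row, col) — two wells at the same position
    on different plates receive the identical signal — emulating stationary
    positional irregularities (distance to light/sound sources) imprinted as
    high-frequency structure.  ``amplitude = 0`` is the identity.
    """
    if amplitude < 0:
        raise ValueError("artifact amplitude must be >= 0")
    if amplitude == 0:
        return dataset
    out = dataset.copy()
    length = out.n_frames
    cache: dict[tuple[int, int], np.ndarray] = {}
    rows = out.wells["row"].to_numpy()
    cols = out.wells["col"].to_numpy()
    for i in range(out.n_wells):
        pos = (int(rows[i]), int(cols[i]))
        if pos not in cache:
            cache[pos] = _artifact_component(pos[0], pos[1], length, amplitude)
        out.traces[i] = np.maximum(out.traces[i] + cache[pos], 0.0)
    descriptor = {"kind": "cosine", "frequency": ARTIFACT_FREQ, "amplitude": amplitude,
                  "gradient": "smooth row+col amplitude/phase ramp"}
    if ground_truth is not None:
        ground_truth.artifact_field = descriptor
    out.provenance["artifact"] = descriptor
    return out
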