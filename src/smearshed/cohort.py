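"""Synthetic cohort and smear-scene generation.

The cohort generator emulates the structure of a 10-week observational
longitudinal study: non-pregnant reproductive-aged women examined at
enrolment, week 5 and week 10, each visit yielding one smear with three
per-field complete-cell counts, three cell-aggregate areas, an Amsel
diagnostic group (noBV / aBV / sBV), and a microbiota CST label. Defaults
are calibrated to the published group summaries of such a study: per-group
median counts (91, 35, 158) per 100X field, median aggregate areas
(50,000; 7,000; 220,000) µm², group SCI (0.86, 0.35), group sizes in
proportion 104:71:17 over ~192 samples from 126 women, and CST IV dominant
among BV samples.

The generating model mirrors the analysis models so that parameter
recovery is well-posed, and the noise enters at the level the analysis
models the data: the *slide*. The published medians are medians of the
per-slide mean count and mean aggregate area, so the slide-level log10
intensity is drawn as Laplace (counts) or Normal (areas) around the group
location plus a Gaussian subject effect — making the configured location
the median of the modelled response — and the three per-field measurements
then vary around the slide intensity (Poisson field counts; small
lognormal jitter for areas). The superficial count is Binomial with a
subject random intercept on the logit scale, drawn only for samples
passing the <=50 mean-count SCI gate.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit, logit

from .errors import ConfigError, GenerationError
from .morphometry import CellObservation, SmearScene
from .geometry import polygon_area
from .records import AmselGroup, CSTLabel, SmearRecord, StudyTable

GROUPS = ("noBV", "aBV", "sBV")

#: Composition of the non-CST-IV remainder within each Amsel group
#: (weights over CSTs I, II, III, V). BV groups' non-IV samples are almost
#: exclusively CST III; noBV spreads over the Lactobacillus-dominated CSTs.
NON_CST4_WEIGHTS = {
    "noBV": (0.50, 0.06, 0.38, 0.06),
    "aBV": (0.25, 0.0, 0.75, 0.0),
    "sBV": (0.0, 0.0, 1.0, 0.0),
}
NON_CST4_LABELS = (CSTLabel.I, CSTLabel.II, CSTLabel.III, CSTLabel.V)


def _round6(x: float) -> float:
    """Round to 6 significant digits — the CSV real precision."""
    return float(format(x, ".6g"))


@dataclass
class CohortConfig:
    """All knobs of the synthetic study. Defaults are the study conditions."""

    n_subjects: int = 126
    visit_weeks: tuple[int, ...] = (0, 5, 10)
    #: probability a scheduled visit actually yields a usable smear;
    #: default makes the expected cohort size ~192 samples from 126 women.
    attendance_prob: float = 192.0 / 378.0
    group_probs: tuple[float, float, float] = (104 / 192, 71 / 192, 17 / 192)
    #: per-group location of log10 cells/100X field (noBV, aBV, sBV)
    count_location_log10: tuple[float, float, float] = (
        math.log10(91.0),
        math.log10(35.0),
        math.log10(158.0),
    )
    count_laplace_scale: float = 0.15
    subject_sd: float = 0.10
    aggregate_median_um2: tuple[float, float, float] = (50_000.0, 7_000.0, 220_000.0)
    aggregate_log10_sd: float = 0.30
    #: within-slide (field-to-field) log10 spread of the three measured
    #: aggregate outlines around the slide-level intensity
    aggregate_within_log10_sd: float = 0.10
    #: median-subject superficial-cell probability per group; sBV smears are
    #: essentially never SCI-eligible, but a value is needed for rare draws.
    sci_prob: tuple[float, float, float] = (0.86, 0.35, 0.86)
    sci_subject_logit_sd: float = 0.4
    cst4_prob_given_group: tuple[float, float, float] = (31 / 104, 62 / 71, 13 / 17)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be non-negative")
        if not self.visit_weeks:
            raise ConfigError("at least one visit week is required")
        if abs(sum(self.group_probs) - 1.0) > 1e-9:
            raise ConfigError(f"group_probs must sum to 1, got {sum(self.group_probs)}")
        for name in ("attendance_prob",):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        for name, probs in (
            ("group_probs", self.group_probs),
            ("sci_prob", self.sci_prob),
            ("cst4_prob_given_group", self.cst4_prob_given_group),
        ):
            if any(not 0 <= p <= 1 for p in probs):
                raise ConfigError(f"{name} entries must lie in [0, 1]: {probs}")
        for name in (
            "count_laplace_scale",
            "subject_sd",
            "aggregate_log10_sd",
            "aggregate_within_log10_sd",
            "sci_subject_logit_sd",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if any(a <= 0 for a in self.aggregate_median_um2):
            raise ConfigError("aggregate medians must be strictly positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        kwargs = {}
        for f_ in cls.__dataclass_fields__:
            if f_ in data:
                v = data[f_]
                kwargs[f_] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Generating parameters and latent variables behind one synthetic table.

    Sufficient to recompute every observation's generating distribution:
    the config, per-subject random effects (count intercept ``b`` on the
    log10 scale, SCI intercept ``u`` on the logit scale), and per-sample
    latent group assignments and locations.
    """

    config: CohortConfig
    subject_ids: list[str]
    b: np.ndarray  # (n_subjects,) count random effects
    u: np.ndarray  # (n_subjects,) SCI random effects
    sample_subject: list[str]
    sample_group: list[str]
    sample_count_location: np.ndarray  # log10 scale, incl. subject effect
    sample_sci_prob: np.ndarray  # NaN where the SCI was not drawn

    def to_json(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        payload = {
            "config": self.config.to_dict(),
            "subject_ids": self.subject_ids,
            "b": self.b.tolist(),
            "u": self.u.tolist(),
            "sample_subject": self.sample_subject,
            "sample_group": self.sample_group,
            "sample_count_location": self.sample_count_location.tolist(),
            "sample_sci_prob": [
                None if not np.isfinite(p) else p for p in self.sample_sci_prob
            ],
        }
        path.write_text(json.dumps(payload), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GroundTruth":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            config=CohortConfig.from_dict(data["config"]),
            subject_ids=data["subject_ids"],
            b=np.asarray(data["b"], dtype=float),
            u=np.asarray(data["u"], dtype=float),
            sample_subject=data["sample_subject"],
            sample_group=data["sample_group"],
            sample_count_location=np.asarray(data["sample_count_location"], dtype=float),
            sample_sci_prob=np.asarray(
                [np.nan if p is None else p for p in data["sample_sci_prob"]], dtype=float
            ),
        )


def generate_cohort(config: CohortConfig) -> tuple[StudyTable, GroundTruth]:
    """Draw a synthetic measurement table plus its generating ground truth.

    Per subject: count intercept ``b_i ~ Normal(0, subject_sd)`` and SCI
    intercept ``u_i ~ Normal(0, sci_subject_logit_sd)``. Per attended
    visit: Amsel group and CST from the configured probabilities; a
    slide-level count intensity ``10**z`` with
    ``z ~ Laplace(loc_g + b_i, scale)`` and three field counts drawn
    Poisson around it; a slide-level aggregate intensity ``10**w`` with
    ``w ~ Normal(log10 median_g, aggregate_log10_sd)`` and three measured
    areas log-normally jittered around it
    (``aggregate_within_log10_sd``). Samples whose mean field count passes the <=50 gate get
    ``total_cells_scored`` equal to the pooled field count and a Binomial
    superficial count with success probability ``expit(logit(p_g) + u_i)``.
    Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    group_locs = dict(zip(GROUPS, config.count_location_log10))
    agg_locs = dict(zip(GROUPS, (math.log10(m) for m in config.aggregate_median_um2)))
    sci_logits = dict(zip(GROUPS, (logit(p) for p in config.sci_prob)))
    cst4 = dict(zip(GROUPS, config.cst4_prob_given_group))

    subject_ids = [f"S{i:04d}" for i in range(config.n_subjects)]
    b = rng.normal(0.0, config.subject_sd, size=config.n_subjects)
    u = rng.normal(0.0, config.sci_subject_logit_sd, size=config.n_subjects)

    records: list[SmearRecord] = []
    samp_subject: list[str] = []
    samp_group: list[str] = []
    samp_loc: list[float] = []
    samp_p: list[float] = []
    for i, sid in enumerate(subject_ids):
        for week in config.visit_weeks:
            if rng.random() > config.attendance_prob:
                continue
            group = GROUPS[rng.choice(3, p=config.group_probs)]
            if rng.random() < cst4[group]:
                cst = CSTLabel.IV
            else:
                cst = NON_CST4_LABELS[
                    rng.choice(4, p=np.asarray(NON_CST4_WEIGHTS[group]) /
                               sum(NON_CST4_WEIGHTS[group]))
                ]
            loc = group_locs[group] + b[i]
            z = rng.laplace(loc, config.count_laplace_scale)
            counts = tuple(int(c) for c in rng.poisson(10.0 ** z, size=3))
            w = rng.normal(agg_locs[group], config.aggregate_log10_sd)
            w_fields = rng.normal(w, config.aggregate_within_log10_sd, size=3)
            areas = tuple(_round6(10.0 ** wf) for wf in w_fields)
            nugent = int(rng.integers(0, 4) if group == "noBV" else rng.integers(7, 11))
            superficial = total = None
            p_sample = np.nan
            if sum(counts) / 3.0 <= 50.0 and sum(counts) > 0:
                total = int(sum(counts))
                p_sample = float(expit(sci_logits[group] + u[i]))
                superficial = int(rng.binomial(total, p_sample))
            records.append(
                SmearRecord(
                    subject_id=sid,
                    visit_week=week,
                    amsel_group=AmselGroup(group),
                    nugent_score=nugent,
                    cst=cst,
                    field_counts=counts,
                    aggregate_areas_um2=areas,
                    superficial_count=superficial,
                    total_cells_scored=total,
                )
            )
            samp_subject.append(sid)
            samp_group.append(group)
            samp_loc.append(loc)
            samp_p.append(p_sample)

    table = StudyTable(records, source=f"synthetic:seed={config.seed}")
    truth = GroundTruth(
        config=config,
        subject_ids=subject_ids,
        b=b,
        u=u,
        sample_subject=samp_subject,
        sample_group=samp_group,
        sample_count_location=np.asarray(samp_loc),
        sample_sci_prob=np.asarray(samp_p),
    )
    return table, truth


# ---------------------------------------------------------------------------
# scene generation

#: nominal 100X field (µm); the published micrograph scale bar fixes the
#: scale but not the absolute frame, so this is the package's frame choice.
DEFAULT_FIELD = (1340.0, 1000.0)

# per-class shape recipes: (n vertices, area range µm², nucleus fraction,
# radial jitter). Few-vertex outlines have angular margins (high angularity);
# many-vertex outlines are near-circular (low angularity). The recipes are
# separable under the default classifier thresholds.
_CLASS_SHAPES = {
    "superficial": (8, (2400.0, 3600.0), 0.04, 0.03),
    "intermediate": (24, (1000.0, 1800.0), 0.18, 0.01),
    "parabasal": (16, (350.0, 700.0), 0.45, 0.01),
}

_GRID_PITCH = 85.0
_EDGE_MARGIN = 85.0
_MAX_CELL_RADIUS = 38.0


def _regular_polygon(n: int, area: float, center: tuple[float, float],
                     rng: np.random.Generator, jitter: float, phase: float) -> np.ndarray:
    theta = phase + 2.0 * np.pi * np.arange(n) / n
    r = 1.0 + rng.uniform(-jitter, jitter, size=n)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    # rescale so the polygon area is exactly `area`
    pts *= math.sqrt(area / polygon_area(pts))
    return pts + np.asarray(center)


def _make_cell(cls: str, center: tuple[float, float], rng: np.random.Generator) -> CellObservation:
    n, (a_lo, a_hi), f_nuc, jitter = _CLASS_SHAPES[cls]
    area = rng.uniform(a_lo, a_hi)
    phase = rng.uniform(0, 2 * np.pi)
    outline = _regular_polygon(n, area, center, rng, jitter, phase)
    nucleus = _regular_polygon(12, f_nuc * area, center, rng, 0.0, phase)
    return CellObservation(outline, nucleus, true_class=cls)


def _blob_outline(area: float, center: tuple[float, float],
                  rng: np.random.Generator) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(40) / 40
    phi, psi = rng.uniform(0, 2 * np.pi, size=2)
    r = 1.0 + 0.25 * np.sin(3 * theta + phi) + 0.12 * np.sin(7 * theta + psi)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    pts *= math.sqrt(area / polygon_area(pts))
    return pts + np.asarray(center)


def generate_scene(
    n_complete: int,
    n_straddling: int,
    class_mix: Sequence[float],
    aggregate_area_um2: float,
    seed: int,
    field_bounds: tuple[float, float] = DEFAULT_FIELD,
) -> SmearScene:
    """Construct a vector field scene with known ground truth.

    Places ``n_complete`` non-overlapping cells fully inside the field and
    ``n_straddling`` cells crossing the boundary (excluded from complete
    counts), draws each cell's maturity class from ``class_mix``
    (superficial, intermediate, parabasal), and adds one aggregate outline
    whose area equals ``aggregate_area_um2`` up to float rounding.
    """
    if n_complete < 0 or n_straddling < 0:
        raise GenerationError("cell counts must be non-negative")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
        raise GenerationError(f"class_mix must be 3 probabilities summing to 1: {class_mix}")
    if aggregate_area_um2 <= 0:
        raise GenerationError("aggregate area must be positive")
    w, h = field_bounds
    rng = np.random.default_rng(seed)

    xs = np.arange(_EDGE_MARGIN, w - _EDGE_MARGIN + 1e-9, _GRID_PITCH)
    ys = np.arange(_EDGE_MARGIN, h - _EDGE_MARGIN + 1e-9, _GRID_PITCH)
    slots = [(x, y) for x in xs for y in ys]
    if n_complete > len(slots):
        raise GenerationError(
            f"cannot pack {n_complete} complete cells into a "
            f"{w:.0f}x{h:.0f} µm field (max {len(slots)})"
        )
    order = rng.permutation(len(slots))[:n_complete]

    cells: list[CellObservation] = []
    for idx in order:
        x, y = slots[idx]
        center = (x + rng.uniform(-4, 4), y + rng.uniform(-4, 4))
        cls = ("superficial", "intermediate", "parabasal")[rng.choice(3, p=mix)]
        cells.append(_make_cell(cls, center, rng))

    # straddling cells sit with their centre on the field boundary, so part
    # of the outline falls outside the image
    perim_step = 2.5 * _MAX_CELL_RADIUS
    edge_positions: list[tuple[float, float]] = []
    t = perim_step / 2
    perimeter = 2 * (w + h)
    while t < perimeter and len(edge_positions) < n_straddling * 3 + 1:
        if t < w:
            edge_positions.append((t, 0.0))
        elif t < w + h:
            edge_positions.append((w, t - w))
        elif t < 2 * w + h:
            edge_positions.append((2 * w + h - t, h))
        else:
            edge_positions.append((0.0, perimeter - t))
        t += perim_step
    if n_straddling > len(edge_positions):
        raise GenerationError(f"cannot place {n_straddling} straddling cells")
    for idx in rng.permutation(len(edge_positions))[:n_straddling]:
        cls = ("superficial", "intermediate", "parabasal")[rng.choice(3, p=mix)]
        cells.append(_make_cell(cls, edge_positions[idx], rng))

    aggregate = _blob_outline(aggregate_area_um2, (w / 2.0, h / 2.0), rng)
    return SmearScene(field_bounds=field_bounds, cells=tuple(cells),
                      aggregate_outlines=(aggregate,))


#: Reproducible scene archetypes mirroring the published example micrographs:
#: (a) dense superficial singletons, no BV; (b) dense superficial cells with a
#: very large aggregate, symptomatic BV; (c) sparse, predominantly superficial,
#: no BV; (d) sparse mixed-maturity smear, asymptomatic BV.
SCENE_PRESETS = {
    "fig1a": dict(n_complete=120, n_straddling=8, class_mix=(1.0, 0.0, 0.0),
                  aggregate_area_um2=5_000.0),
    "fig1b": dict(n_complete=120, n_straddling=8, class_mix=(1.0, 0.0, 0.0),
                  aggregate_area_um2=220_000.0),
    "fig1c": dict(n_complete=35, n_straddling=3, class_mix=(0.9, 0.1, 0.0),
                  aggregate_area_um2=50_000.0),
    "fig1d": dict(n_complete=30, n_straddling=3, class_mix=(0.40, 0.35, 0.25),
                  aggregate_area_um2=7_000.0),
}


def generate_preset_scene(preset: str, seed: int) -> SmearScene:
    if preset not in SCENE_PRESETS:
        raise GenerationError(
            f"unknown preset {preset!r}; choose from {sorted(SCENE_PRESETS)}"
        )
    return generate_scene(seed=seed, **SCENE_PRESETS[preset])
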