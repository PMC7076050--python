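"""End-to-end analysis: descriptives, model fits, contrasts, FDR, export.

The pipeline mirrors how a cell-shedding smear study is analysed: per-group
medians and IQRs of the mean cell count, mean aggregate area and SCI
(overall and within the CST IV stratum), CST-by-group frequency tables,
Laplace location fits for counts and aggregate areas, the binomial SCI
model on the gated subset, an optional within-woman Poisson comparison for
subjects seen in both BV groups, and a single Benjamini-Hochberg family
over all contrasts produced in the run.

Units of analysis for descriptives are samples, not women; within-woman
correlation is handled inside the Bayesian models via subject intercepts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .errors import PipelineError
from .mcmc import McmcConfig
from .models import (
    ContrastResult,
    adjust_family,
    contrast_tail_p,
    fit_location_model,
    fit_sci_model,
    fit_within_subject_poisson,
    paired_delta_result,
)
from .records import SCI_COUNT_GATE, StudyTable

log = logging.getLogger("smearshed")

DEFAULT_CONTRASTS = (("noBV", "sBV"), ("noBV", "aBV"), ("sBV", "aBV"))
DEFAULT_SCI_CONTRASTS = (("noBV", "aBV"),)
OUTCOMES = ("mean_count", "mean_aggregate_area_um2", "sci")


@dataclass
class AnalysisConfig:
    """Everything needed to re-run one analysis bit-identically."""

    input_path: Optional[str] = None
    outcomes: tuple[str, ...] = OUTCOMES
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    sci_contrasts: tuple[tuple[str, str], ...] = DEFAULT_SCI_CONTRASTS
    strata: tuple[str, ...] = ("overall", "CST IV")
    sci_gate: float = SCI_COUNT_GATE
    quantile_convention: str = "linear"
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    output_dir: Optional[str] = None
    seed: int = 0
    paired_groups: tuple[str, str] = ("aBV", "sBV")
    min_paired_subjects: int = 2
    #: abort on R-hat >= 1.05 (disable only for short exploratory chains)
    check_convergence: bool = True

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "outcomes": list(self.outcomes),
            "contrasts": [list(c) for c in self.contrasts],
            "sci_contrasts": [list(c) for c in self.sci_contrasts],
            "strata": list(self.strata),
            "sci_gate": self.sci_gate,
            "quantile_convention": self.quantile_convention,
            "mcmc": {
                "n_chains": self.mcmc.n_chains,
                "n_iterations": self.mcmc.n_iterations,
                "n_warmup": self.mcmc.n_warmup,
                "target_accept": self.mcmc.target_accept,
            },
            "seed": self.seed,
            "paired_groups": list(self.paired_groups),
            "min_paired_subjects": self.min_paired_subjects,
            "check_convergence": self.check_convergence,
        }


@dataclass
class ResultsBundle:
    """All tabular outputs of one pipeline run plus the run manifest."""

    descriptives: pd.DataFrame
    contrasts: pd.DataFrame
    cst_frequencies: pd.DataFrame
    manifest: dict

    def write(self, out_dir: Union[str, Path]) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            for name, frame in (
                ("descriptives.csv", self.descriptives),
                ("contrasts.csv", self.contrasts),
                ("cst_frequencies.csv", self.cst_frequencies),
            ):
                path = out_dir / name
                frame.to_csv(path, index=False, float_format="%.6g")
                written.append(path)
            path = out_dir / "manifest.json"
            path.write_text(
                json.dumps(self.manifest, indent=2, sort_keys=True), encoding="utf-8"
            )
            written.append(path)
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
        return out_dir


# ---------------------------------------------------------------------------
# descriptive statistics


def group_summary(
    table: StudyTable,
    outcome: str,
    groups: Sequence[str] = ("noBV", "aBV", "sBV"),
    stratum: Optional[str] = None,
) -> pd.DataFrame:
    """Per-group n, median and IQR of one outcome.

    Quantiles use linear interpolation between order statistics. Groups
    with no data for the outcome are omitted with a warning, never
    fabricated. ``stratum`` restricts to one CST label (e.g. ``"IV"``).
    """
    frame = table.to_frame()
    if stratum is not None:
        frame = frame[frame["cst"] == stratum]
    rows = []
    for g in groups:
        vals = frame.loc[frame["amsel_group"] == g, outcome].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            log.warning("group %s has no data for outcome %s; omitted", g, outcome)
            continue
        q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75], method="linear")
        rows.append(
            {
                "group": g,
                "stratum": stratum or "overall",
                "outcome": outcome,
                "n": int(vals.size),
                "median": float(med),
                "q25": float(q25),
                "q75": float(q75),
            }
        )
    return pd.DataFrame(rows, columns=["group", "stratum", "outcome", "n",
                                       "median", "q25", "q75"])


def cst_frequency_table(table: StudyTable) -> pd.DataFrame:
    """Counts and percentages of each observed CST within each Amsel group.

    Percentages are rounded to 2 decimals with the observed group total as
    denominator; unobserved group x CST combinations produce no rows.
    """
    frame = table.to_frame()
    rows = []
    for g in ("noBV", "aBV", "sBV"):
        sub = frame[frame["amsel_group"] == g]
        total = len(sub)
        if total == 0:
            continue
        counts = sub["cst"].value_counts()
        for cst in ("I", "II", "III", "IV", "V"):
            c = int(counts.get(cst, 0))
            if c == 0:
                continue
            rows.append(
                {
                    "group": g,
                    "cst": cst,
                    "count": c,
                    "group_total": total,
                    "percent": round(100.0 * c / total, 2),
                }
            )
    return pd.DataFrame(rows, columns=["group", "cst", "count", "group_total", "percent"])


# ---------------------------------------------------------------------------
# full pipeline


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


def _stratify(table: StudyTable, stratum: str) -> StudyTable:
    if stratum == "overall":
        return table
    if stratum == "CST IV":
        return table.filter(lambda r: r.cst.value == "IV")
    raise PipelineError(f"unknown stratum {stratum!r}")


def run_pipeline(config: AnalysisConfig, table: Optional[StudyTable] = None) -> ResultsBundle:
    """Execute the full analysis; deterministic given the config seed.

    Stages, in order: validation, descriptives (per stratum), Laplace
    location fits for counts and aggregate areas, binomial SCI fit on the
    gated subset, optional paired Poisson fit when subjects observed in
    both groups of ``config.paired_groups`` exist, contrasts, single-family
    BH-FDR, export (when ``config.output_dir`` is set).
    """
    stage = "validation"
    try:
        if table is None:
            from .io import read_study_table

            if config.input_path is None:
                raise PipelineError("no input table given")
            table = read_study_table(config.input_path, strict=True)
        if len(table) == 0:
            raise PipelineError("input table is empty")

        stage = "descriptives"
        desc_frames = []
        for stratum in config.strata:
            sub = _stratify(table, stratum)
            for outcome in config.outcomes:
                desc_frames.append(
                    group_summary(sub, outcome,
                                  stratum=None if stratum == "overall" else "IV")
                )
        descriptives = pd.concat(desc_frames, ignore_index=True)
        cst_freq = cst_frequency_table(table)

        stage = "model fits"
        seeds = iter(_child_seeds(config.seed, 64))

        def mcmc_with_seed() -> McmcConfig:
            m = config.mcmc
            return McmcConfig(m.n_chains, m.n_iterations, m.n_warmup,
                              next(seeds), m.target_accept)

        results: list[dict] = []

        def add(outcome: str, stratum: str, res: ContrastResult) -> None:
            results.append({"outcome": outcome, "stratum": stratum, **res.__dict__})

        for stratum in config.strata:
            sub = _stratify(table, stratum)
            for outcome in ("mean_count", "mean_aggregate_area_um2"):
                if outcome not in config.outcomes:
                    continue
                post = fit_location_model(sub, response=outcome, mcmc=mcmc_with_seed(),
                                          check=config.check_convergence)
                for g1, g2 in config.contrasts:
                    add(outcome, stratum, contrast_tail_p(post, g1, g2))
            if "sci" in config.outcomes:
                gated = sub.filter(lambda r: r.mean_count <= config.sci_gate)
                assert all(r.mean_count <= config.sci_gate for r in gated)
                sci_groups = sorted(
                    {r.amsel_group.value for r in gated if r.superficial_count is not None}
                )
                wanted = {g for pair in config.sci_contrasts for g in pair}
                if wanted <= set(sci_groups):
                    post = fit_sci_model(gated, mcmc=mcmc_with_seed(),
                                         groups=sorted(wanted),
                                         check=config.check_convergence)
                    for g1, g2 in config.sci_contrasts:
                        add("sci", stratum, contrast_tail_p(post, g1, g2))
                else:
                    log.warning(
                        "stratum %s: SCI contrast groups %s not all represented; skipped",
                        stratum, sorted(wanted),
                    )

        stage = "paired comparison"
        ga, gb = config.paired_groups
        by_subject: dict[str, set[str]] = {}
        for r in table:
            by_subject.setdefault(r.subject_id, set()).add(r.amsel_group.value)
        paired_ids = [s for s, gs in by_subject.items() if {ga, gb} <= gs]
        if len(paired_ids) >= config.min_paired_subjects:
            paired = table.filter(
                lambda r: r.subject_id in paired_ids and r.amsel_group.value in (ga, gb)
            )
            for outcome in ("mean_count", "mean_aggregate_area_um2"):
                if outcome not in config.outcomes:
                    continue
                post = fit_within_subject_poisson(
                    paired, response=outcome, groups=(ga, gb), mcmc=mcmc_with_seed(),
                    check=config.check_convergence,
                )
                add(outcome, "paired", paired_delta_result(post))
        else:
            log.info("only %d subject(s) observed in both %s and %s; paired model skipped",
                     len(paired_ids), ga, gb)

        stage = "FDR adjustment"
        family = [
            ContrastResult(**{k: row[k] for k in
                              ("label", "mean", "sd", "ci_low", "ci_high",
                               "p", "p_empirical", "q")})
            for row in results
        ]
        adjusted = adjust_family(family)
        contrasts = pd.DataFrame(
            [
                {
                    "outcome": row["outcome"],
                    "stratum": row["stratum"],
                    "contrast": res.label,
                    "mean": res.mean,
                    "sd": res.sd,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "p_empirical": res.p_empirical,
                    "q": res.q,
                }
                for row, res in zip(results, adjusted)
            ]
        )

        stage = "export"
        cfg_dict = config.to_dict()
        manifest = {
            "config": cfg_dict,
            "config_hash": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()
            ).hexdigest(),
            "seed": config.seed,
            "n_samples": len(table),
            "n_subjects": len(table.subjects()),
            "package_version": __version__,
            "quantile_convention": config.quantile_convention,
        }
        bundle = ResultsBundle(descriptives, contrasts, cst_freq, manifest)
        if config.output_dir is not None:
            bundle.write(config.output_dir)
        return bundle
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
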