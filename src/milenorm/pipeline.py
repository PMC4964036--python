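"""Pipeline orchestration: screen -> score -> norm -> compare -> reliability.

A run is a pure function of (inputs, config, seed): each stage logs its
record counts, writes its artifact into the run directory, and any failure
aborts with the stage name. Thresholds default to the study's rules
(Hosmer-Lemeshow gate at 5%, >10% relative difference clinically
significant, 70% agreement floor).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anthro, compare, norming, reliability, scoring
from .instrument import (
    DOMAIN_NAMES,
    DOMAINS,
    Instrument,
    NormsTable,
    ValidationError,
    read_instrument,
    read_lms_reference,
    read_norms,
    read_responses,
    read_roster,
    write_norms,
    write_roster,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is inconsistent or incomplete."""


@dataclass
class PipelineConfig:
    instrument_path: str
    roster_path: str
    responses_path: str
    out_dir: str
    lms_path: str | None = None
    reference_norms_path: str | None = None
    stages: tuple[str, ...] = ("screen", "score", "norm", "compare", "reliability")
    hl_alpha: float = norming.HL_ALPHA
    hl_groups: int = norming.HL_GROUPS
    min_n: int = norming.MIN_N
    comparison_threshold: float = compare.SIGNIFICANT_REL_DIFF
    agreement_floor: float = reliability.AGREEMENT_FLOOR
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def validate(self):
        if not 0 < self.hl_alpha < 1:
            raise ConfigError("hl_alpha must lie in (0, 1)")
        if not 0 < self.comparison_threshold < 1:
            raise ConfigError("comparison_threshold must lie in (0, 1)")
        if not 0 <= self.agreement_floor <= 100:
            raise ConfigError("agreement_floor must lie in [0, 100]")
        unknown = set(self.stages) - {"screen", "score", "norm", "compare", "reliability"}
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        for path in (self.instrument_path, self.roster_path, self.responses_path):
            if not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")
        if "screen" in self.stages and (
            self.lms_path is None or not Path(self.lms_path).exists()
        ):
            raise ConfigError("screen stage enabled but no LMS reference file")
        if "compare" in self.stages and (
            self.reference_norms_path is None
            or not Path(self.reference_norms_path).exists()
        ):
            raise ConfigError("compare stage enabled but no reference norms file")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a summary dict of stage outputs."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("milenorm")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"stages": list(config.stages), "seed": config.seed}
    stage = "load"
    try:
        instrument = read_instrument(config.instrument_path)
        roster = read_roster(config.roster_path)
        responses = read_responses(config.responses_path)
        logger.info("loaded %d items, %d children, %d responses",
                    len(instrument), len(roster), len(responses))

        if "screen" in config.stages:
            stage = "screen"
            lms = read_lms_reference(config.lms_path)
            records = anthro.compute_anthro(roster, lms)
            roster, report = anthro.apply_exclusions(roster, records)
            (out_dir / "exclusions.json").write_text(json.dumps(report, indent=2))
            write_roster(roster, out_dir / "kept.csv")
            summary["screen"] = report
            logger.info("screen: retained %d of %d", report["n_retained"], report["n_input"])

        norms_for_scoring = None
        if config.reference_norms_path and Path(config.reference_norms_path).exists():
            norms_for_scoring = read_norms(config.reference_norms_path)

        scored = scores = None
        local_norms: NormsTable | None = None
        if "score" in config.stages or "norm" in config.stages or "reliability" in config.stages:
            stage = "score"
            if norms_for_scoring is None:
                raise ConfigError("scoring needs a norms file for expected passes "
                                  "(set reference_norms_path)")
            scored, scores = scoring.score_cohort(
                instrument, norms_for_scoring, roster, responses
            )
            scored.to_csv(out_dir / "scored.csv", index=False)
            scores.to_csv(out_dir / "domain_scores.csv", index=False)
            summary["score"] = {"n_scored_rows": len(scored)}
            logger.info("score: %d scored rows", len(scored))

        if "norm" in config.stages:
            stage = "norm"
            local_norms, diagnostics, _models = norming.build_norms(
                instrument, scored,
                min_n=config.min_n, hl_alpha=config.hl_alpha, hl_groups=config.hl_groups,
            )
            write_norms(local_norms, out_dir / "norms.csv")
            diag_payload = [
                {"item_code": d.item_code, "hl_statistic": d.hl_statistic,
                 "hl_df": d.hl_df, "hl_p": d.hl_p,
                 "refit_triggered": d.refit_triggered, "model_form": d.model_form,
                 "n_used": d.n_used, "notes": d.notes}
                for d in diagnostics
            ]
            (out_dir / "diagnostics.json").write_text(json.dumps(diag_payload, indent=2))
            summary["norm"] = {
                "n_items_normed": len(local_norms),
                "n_refits": sum(d.refit_triggered for d in diagnostics),
            }
            logger.info("norm: %d items normed", len(local_norms))

        if "compare" in config.stages:
            stage = "compare"
            reference = read_norms(config.reference_norms_path)
            if local_norms is None:
                raise ConfigError("compare stage needs the norm stage (or local norms)")
            comparison = compare.compare_norms(
                local_norms, reference, threshold=config.comparison_threshold
            )
            comparison.to_csv(out_dir / "comparison.csv", index=False)
            comp_summary = compare.summarize_comparison(
                comparison.set_index("item_code")["flag"], instrument
            )
            (out_dir / "summary.json").write_text(json.dumps(comp_summary, indent=2))
            summary["compare"] = comp_summary
            logger.info("compare: %d differing items", comp_summary["differing"])

        if "reliability" in config.stages:
            stage = "reliability"
            obs_scored = obs_scores = None
            if (responses["rater_role"] == "observer").any():
                obs_scored, obs_scores = scoring.score_cohort(
                    instrument, norms_for_scoring, roster, responses,
                    occasion="test", rater_role="observer",
                )
                has_obs = obs_scored["status"].isin(
                    ("tested_pass", "tested_fail", "refusal", "no_opportunity")
                ).groupby(obs_scored["child_id"]).any()
                keep = set(has_obs[has_obs].index)
                obs_scored = obs_scored[obs_scored["child_id"].isin(keep)]
                obs_scores = obs_scores[obs_scores["child_id"].isin(keep)]
            re_scored = re_scores = None
            if (responses["occasion"] == "retest").any():
                retest_roster = [c for c in roster if c.retest_date is not None]
                re_scored, re_scores = scoring.score_cohort(
                    instrument, norms_for_scoring, retest_roster, responses,
                    occasion="retest", rater_role="tester",
                )
            tester_scored_sub = scored
            rel = reliability.reliability_report(
                tester_test_scored=tester_scored_sub,
                tester_test_scores=scores,
                observer_test_scored=obs_scored,
                observer_test_scores=obs_scores,
                tester_retest_scored=re_scored,
                tester_retest_scores=re_scores,
                instrument=instrument,
            )
            (out_dir / "reliability.json").write_text(json.dumps(rel, indent=2))
            summary["reliability"] = {
                k: v["band_frequency"] for k, v in rel.items()
                if isinstance(v, dict) and "band_frequency" in v
            }
            logger.info("reliability report written")
    except ConfigError:
        raise
    except ValidationError as exc:
        raise ValidationError(f"stage {stage}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def render_chart(norms: NormsTable, out_path) -> None:
    """Percentile-bar chart: one horizontal bar per item, segmented at the
    25/50/75/90% milestone ages, one panel per domain, age axis in months."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = norms.frame
    domains = [d for d in DOMAINS if any(str(c).startswith(d) for c in frame.index)]
    if not domains:
        domains = ["PS"]
    fig, axes = plt.subplots(
        1, len(domains),
        figsize=(4.2 * len(domains), 0.22 * max(len(frame), 8) + 1.5),
        squeeze=False,
    )
    colors = ["#c6dbef", "#6baed6", "#2171b5", "#08306b"]
    for ax, dom in zip(axes[0], domains):
        codes = [c for c in frame.index if str(c).startswith(dom)]
        for y, code in enumerate(codes):
            p = [norms.percentile_months(code, q) for q in (25, 50, 75, 90)]
            if p[3] <= 0:
                ax.plot([0], [y], marker="|", color=colors[-1])
                ax.annotate("birth", (0.3, y), fontsize=5, va="center")
                continue
            segs = [(0 if i == 0 else p[i - 1], p[i]) for i in range(4)]
            for (lo, hi), col in zip(segs, colors):
                ax.barh(y, hi - lo, left=lo, height=0.7, color=col, edgecolor="none")
        ax.set_yticks(range(len(codes)))
        ax.set_yticklabels(codes, fontsize=5)
        ax.invert_yaxis()
        ax.set_title(DOMAIN_NAMES[dom], fontsize=9)
        ax.set_xlabel("age (months)", fontsize=7)
        ax.tick_params(axis="x", labelsize=6)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
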