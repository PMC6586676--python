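"""File formats, run configuration and the end-to-end pipeline.

The site-table dialect is a UTF-8, tab-delimited text file. Leading
``#species<TAB><id><TAB><A|B|focal>`` comment lines assign each
individual to a panel; the header row names ``site_id, allele1, allele2``
followed by paired count columns ``<id>__a1`` and ``<id>__a2``. Counts
are nonnegative integers and every site is biallelic by construction
(exactly the two allele columns).

``run_pipeline`` executes the full analysis in order — classify, filter,
tally focal allele matches, test scenarios, trace the ancestry
likelihood — writing each product as TSV plus a human-readable summary,
with all randomness taken from the config seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .coverage import CoverageProfile
from .inference import AlleleCounts, AncestryEstimator
from .simulate import DEFAULT_SCENARIOS
from .sites import FilterConfig, SiteTable, apply_filters, classify_sites

__all__ = [
    "SiteTableFormatError",
    "read_site_table",
    "write_site_table",
    "read_coverage_sites",
    "read_coverage_scaffolds",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
]

logger = logging.getLogger("hybricov")


class SiteTableFormatError(ValueError):
    """Malformed site-table file; message names the offending line."""


def write_site_table(table: SiteTable, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for iid, sp in table.species.items():
            fh.write(f"#species\t{iid}\t{sp}\n")
        table.data.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_site_table(path) -> SiteTable:
    """Parse the TSV dialect back into a SiteTable (lossless round-trip)."""
    path = Path(path)
    species: dict[str, str] = {}
    n_meta = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 or parts[0] != "#species":
                raise SiteTableFormatError(
                    f"{path}:{n_meta}: expected '#species<TAB>id<TAB>label'"
                )
            species[parts[1]] = parts[2]
    if not species:
        raise SiteTableFormatError(f"{path}:1: no #species annotation lines")

    df = pd.read_csv(path, sep="\t", skiprows=n_meta)
    header_line = n_meta + 1
    expected = ["site_id", "allele1", "allele2"] + [
        f"{iid}__{s}" for iid in species for s in ("a1", "a2")
    ]
    if list(df.columns) != expected:
        extra = [c for c in df.columns if c not in expected]
        missing = [c for c in expected if c not in df.columns]
        detail = []
        if extra:
            detail.append(f"unexpected columns {extra}")
        if missing:
            detail.append(f"missing columns {missing}")
        if not detail:
            detail.append("column order differs from the declared individuals")
        if any("allele" in c for c in extra):
            detail.append("sites must be biallelic: exactly two allele columns")
        raise SiteTableFormatError(f"{path}:{header_line}: " + "; ".join(detail))

    count_cols = expected[3:]
    counts = df[count_cols]
    for col in count_cols:
        bad = counts[col] < 0
        if not pd.api.types.is_integer_dtype(counts[col]):
            nonint = ~counts[col].map(lambda v: float(v).is_integer())
            if nonint.any():
                row = int(counts[col].index[nonint][0])
                raise SiteTableFormatError(
                    f"{path}:{header_line + 1 + row}: non-integer count in {col!r}"
                )
            df[col] = df[col].astype(int)
        if bad.any():
            row = int(bad.idxmax())
            raise SiteTableFormatError(
                f"{path}:{header_line + 1 + row}: negative count in {col!r}"
            )
    return SiteTable(df, species)


def read_coverage_sites(path) -> CoverageProfile:
    """Two-column TSV (site_class in {X, AUTO}, depth) -> CoverageProfile."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["site_class", "depth"]:
        raise SiteTableFormatError(f"{path}:1: expected columns site_class, depth")
    x = df.loc[df["site_class"] == "X", "depth"].to_numpy(float)
    auto = df.loc[df["site_class"] == "AUTO", "depth"].to_numpy(float)
    return CoverageProfile(x, auto, provenance=str(path))


def read_coverage_scaffolds(path) -> CoverageProfile:
    """Per-scaffold summary TSV (scaffold, site_class, n_sites, mean_depth).

    Scaffold mean depths are used as values weighted by scaffold site
    counts; resampling then draws scaffold means proportionally to their
    length.
    """
    df = pd.read_csv(path, sep="\t")
    need = ["scaffold", "site_class", "n_sites", "mean_depth"]
    if list(df.columns[:4]) != need:
        raise SiteTableFormatError(f"{path}:1: expected columns {need}")
    x = df[df["site_class"] == "X"]
    auto = df[df["site_class"] == "AUTO"]
    return CoverageProfile(
        x["mean_depth"].to_numpy(float),
        auto["mean_depth"].to_numpy(float),
        x_weights=x["n_sites"].to_numpy(float),
        auto_weights=auto["n_sites"].to_numpy(float),
        provenance=f"{path} (per-scaffold summary)",
    )


@dataclass
class RunConfig:
    """Everything needed to rerun an analysis deterministically."""

    max_total_depth: int = 9
    min_urd_per_panel: int = 3
    focal_read_rule: str = "exactly_one"
    require_polymorphic: bool = True
    urd_mode: str = "individuals"
    scenarios: Sequence[str] = tuple(DEFAULT_SCENARIOS)
    alpha: float = 0.05
    error_floor: float = 0.001
    grid_step: float = 0.001
    n_reps: int = 100
    sites_per_rep: int = 10_000
    sex_boundary: float = 0.75
    seed: int = 0
    output_dir: str = "hybricov_out"

    def validate(self) -> None:
        self.filter_config().validate()
        if not self.scenarios:
            raise ValueError("scenario set must be nonempty")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            max_total_depth=self.max_total_depth,
            min_urd_per_panel=self.min_urd_per_panel,
            focal_read_rule=self.focal_read_rule,
            require_polymorphic=self.require_polymorphic,
        )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["scenarios"] = list(self.scenarios)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        d["scenarios"] = tuple(d.get("scenarios", DEFAULT_SCENARIOS))
        return cls(**d)


@dataclass
class PipelineResult:
    filtered: SiteTable
    summary: "object"
    counts: AlleleCounts
    estimator: AncestryEstimator
    report: pd.DataFrame
    summary_text: str


def run_pipeline(config: RunConfig, table: SiteTable, out_dir=None) -> PipelineResult:
    """Classify, filter, tally and test; optionally write the report bundle.

    Writes (when ``out_dir`` or ``config.output_dir`` is set to an
    existing/creatable directory): the filtered site table, the class
    summary, the scenario report, the likelihood curve, and a summary.
    Output is a deterministic function of (input, config, seed).
    """
    config.validate()
    logger.info("pipeline start: %d sites, %d individuals", table.n_sites, len(table.species))

    classes = classify_sites(table, urd_mode=config.urd_mode)
    filtered, summary = apply_filters(table, classes, config.filter_config(), config.urd_mode)
    logger.info("filter: %s", summary.breakdown_line())
    if summary.empty:
        logger.warning("no sites retained after filtering")

    kept_ids = set(filtered.data["site_id"])
    kept_classes = classes[classes["site_id"].isin(kept_ids)]
    counts = AlleleCounts.from_classes(kept_classes)
    logger.info("focal allele matches: A=%d B=%d", counts.n_b, counts.n_n)
    if counts.total == 0:
        raise RuntimeError("inference stage: no informative fixed-difference reads")

    est = AncestryEstimator(
        scenarios=tuple(config.scenarios),
        alpha=config.alpha,
        error_floor=config.error_floor,
        grid_step=config.grid_step,
    ).fit(counts)

    lines = [
        summary.breakdown_line(),
        f"focal reads matching species-A allele: {counts.n_b}; species-B allele: {counts.n_n}",
        f"ancestry MLE b = {est.mle_b_:.4f} (2-unit-drop CI {est.ci_[0]:.3f}-{est.ci_[1]:.3f})",
        f"best scenario: {est.best_scenario_}",
        "non-rejected scenarios at alpha="
        f"{config.alpha}: {', '.join(est.accepted_scenarios_) or 'none'}",
    ]
    text = "\n".join(lines) + "\n"

    target = Path(out_dir) if out_dir is not None else (
        Path(config.output_dir) if config.output_dir else None
    )
    if target is not None:
        target.mkdir(parents=True, exist_ok=True)
        write_site_table(filtered, target / "filtered_sites.tsv")
        summary.class_counts.rename(columns={"count_": "count"}).to_csv(
            target / "class_summary.tsv", sep="\t", index=False
        )
        est.scenario_table_.to_csv(target / "scenario_report.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"b": est.curve_.b_grid, "loglik": est.curve_.loglik}
        ).to_csv(target / "likelihood_curve.tsv", sep="\t", index=False)
        (target / "summary.txt").write_text(text, encoding="utf-8")
        config.to_yaml(target / "config.yaml")

    return PipelineResult(
        filtered=filtered,
        summary=summary,
        counts=counts,
        estimator=est,
        report=est.scenario_table_,
        summary_text=text,
    )
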