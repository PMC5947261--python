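"""End-to-end orchestration: filter → ellipses → unions → RINI → models.

The pipeline turns the three input tables (isotope samples, group censuses,
individual attributes; optionally paired-morning weights) into

* a per-individual niche table (sample counts, ellipse areas, RINI and its
  model covariates),
* a per-group niche table (union area, pooled corrected ellipse area, mean
  daily group size, sampling-period length),
* a tidy model-coefficient table plus a JSON summary of the fitted
  mixed/linear models,

and a run log counting records retained and excluded at every filter, so
that input count = retained + excluded at each stage.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, models
from .data import (
    GroupCensus,
    IsotopeSample,
    filter_min_samples,
    modal_group,
    read_census_table,
    read_isotope_table,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "build_rini_table"]


@dataclass
class PipelineConfig:
    """Run configuration; defaults match the study design."""

    isotope_path: str | None = None
    census_path: str | None = None
    attributes_path: str | None = None
    weights_path: str | None = None
    synthetic: bool = False
    seed: int = 0
    p_level: float = 0.95
    min_samples: int = 4
    n_vertices: int = 512
    size_threshold: float = 17.0
    out_dir: str = "results"

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                if value is None:
                    continue
                fh.write(f"{f.name} = {value}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs: dict = {}
        casts = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in casts:
                raise ValueError(f"unknown config key {key!r}")
            if key == "synthetic":
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif key in ("seed", "min_samples", "n_vertices"):
                kwargs[key] = int(raw)
            elif key in ("p_level", "size_threshold"):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class PipelineResult:
    individual_table: pd.DataFrame
    group_table: pd.DataFrame
    model_results: dict[str, models.ModelResult]
    log: list[str] = field(default_factory=list)
    empty: bool = False


def _log(log: list[str], message: str) -> None:
    log.append(message)


def build_rini_table(
    samples: list[IsotopeSample],
    census: list[GroupCensus],
    attributes: pd.DataFrame,
    *,
    min_samples: int = 4,
    p_level: float = 0.95,
    n_vertices: int = 512,
    size_threshold: float = 17.0,
    log: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-individual RINI records and per-group niche summaries.

    Individuals are assigned to their modal group across samples; the RINI
    denominator for a group is the union of the corrected ellipses of its
    members with at least ``min_samples`` samples.  The proportion-sampled
    covariate divides the number of such members by the mean daily head
    count from the census.
    """
    log = log if log is not None else []
    attr = attributes.set_index("individual_id") if len(attributes) else pd.DataFrame()

    by_individual: dict[str, list[IsotopeSample]] = {}
    for s in samples:
        by_individual.setdefault(s.individual_id, []).append(s)

    kept = filter_min_samples(samples, k=min_samples)
    holders = sorted({s.individual_id for s in kept})
    _log(
        log,
        f"filter_min_samples(k={min_samples}): {len(samples)} samples in, "
        f"{len(kept)} retained, {len(samples) - len(kept)} excluded; "
        f"{len(holders)} of {len(by_individual)} individuals retained",
    )

    groups: dict[str, list[str]] = {}
    for ind in holders:
        groups.setdefault(modal_group(by_individual[ind]), []).append(ind)

    ind_rows: list[dict] = []
    grp_rows: list[dict] = []
    n_degenerate = 0
    for group_id in sorted({s.group_id for s in samples}):
        group_samples = [s for s in samples if s.group_id == group_id]
        dates = [s.collection_date for s in group_samples]
        start, end = min(dates), max(dates)
        try:
            mean_size = models.mean_daily_group_size(census, group_id, start, end)
        except models.MissingDataError:
            _log(log, f"group {group_id}: no census coverage, skipped")
            continue
        size_class = models.classify_group_size(mean_size, threshold=size_threshold)
        sampling_days = (end - start).days + 1

        pooled_area = np.nan
        try:
            pooled = geometry.pooled_group_ellipse(
                group_id,
                [(s.d13C, s.d15N) for s in group_samples],
                p_level=p_level,
                n_vertices=n_vertices,
            )
            pooled_area = pooled.area_ell95c
        except (geometry.InsufficientDataError, geometry.DegenerateGeometryError):
            _log(log, f"group {group_id}: pooled ellipse not estimable")

        members = groups.get(group_id, [])
        ellipses = []
        for ind in members:
            pts = [(s.d13C, s.d15N) for s in by_individual[ind]]
            try:
                ellipses.append(
                    geometry.fit_ellipse(ind, pts, p_level=p_level, n_vertices=n_vertices)
                )
            except geometry.DegenerateGeometryError:
                n_degenerate += 1
                _log(log, f"individual {ind}: degenerate sample geometry, excluded")

        union_area = np.nan
        if ellipses:
            niche = geometry.build_group_niche(group_id, ellipses)
            union_area = niche.union_area
            prop = min(len(ellipses) / mean_size, 1.0)
            for rec in geometry.compute_rini(niche):
                row = {
                    "individual_id": rec.individual_id,
                    "group_id": group_id,
                    "n_samples": next(
                        e.n for e in ellipses if e.owner_id == rec.individual_id
                    ),
                    "area_ell95": next(
                        e.area_ell95 for e in ellipses if e.owner_id == rec.individual_id
                    ),
                    "area_ell95c": next(
                        e.area_ell95c for e in ellipses if e.owner_id == rec.individual_id
                    ),
                    "rini": rec.rini,
                    "sqrt_rini": rec.sqrt_rini,
                    "group_size": mean_size,
                    "group_size_class": size_class,
                    "proportion_sampled": prop,
                }
                if len(attr) and rec.individual_id in attr.index:
                    row["sex"] = attr.loc[rec.individual_id, "sex"]
                    row["age_years"] = float(attr.loc[rec.individual_id, "age_years"])
                ind_rows.append(row)

        grp_rows.append(
            {
                "group_id": group_id,
                "group_size": mean_size,
                "group_size_class": size_class,
                "n_samples": len(group_samples),
                "n_rini_individuals": len(ellipses),
                "union_area": union_area,
                "pooled_ell95c": pooled_area,
                "sampling_days": sampling_days,
            }
        )

    if n_degenerate:
        _log(log, f"{n_degenerate} individual(s) excluded for degenerate geometry")
    individual_table = pd.DataFrame(ind_rows)
    group_table = pd.DataFrame(grp_rows)
    _log(
        log,
        f"RINI computed for {len(individual_table)} individuals in "
        f"{individual_table['group_id'].nunique() if len(individual_table) else 0} groups",
    )
    return individual_table, group_table


def fit_rini_models(
    individual_table: pd.DataFrame, group_table: pd.DataFrame
) -> dict[str, models.ModelResult]:
    """The niche-size models: √RINI mixed models and the group-level OLS."""
    out: dict[str, models.ModelResult] = {}
    need = {"sqrt_rini", "group_size", "age_years", "sex", "proportion_sampled"}
    if need <= set(individual_table.columns) and individual_table["group_id"].nunique() >= 2:
        out["rini_continuous"] = models.fit_lmm(
            individual_table,
            "sqrt_rini",
            ["group_size", "age_years", "C(sex)", "proportion_sampled"],
            ["group_id"],
        )
        out["rini_continuous"].transform = "sqrt"
        out["rini_categorical"] = models.fit_lmm(
            individual_table,
            "sqrt_rini",
            ["C(group_size_class, Treatment('small'))", "age_years", "C(sex)", "proportion_sampled"],
            ["group_id"],
        )
        out["rini_categorical"].transform = "sqrt"
    grp = group_table.dropna(subset=["pooled_ell95c"]) if len(group_table) else group_table
    if len(grp) >= 4:
        out["group_ell95c_continuous"] = models.fit_linear_model(
            grp, "pooled_ell95c", ["group_size", "sampling_days"]
        )
        out["group_ell95c_categorical"] = models.fit_linear_model(
            grp,
            "pooled_ell95c",
            ["C(group_size_class, Treatment('small'))", "sampling_days"],
        )
    return out


def fit_weight_models(weight_frame: pd.DataFrame) -> dict[str, models.ModelResult]:
    """The body-condition models: daily weight change and overall weight."""
    df = weight_frame.copy()
    df["weight_second_g"] = pd.to_numeric(df["weight_second_g"], errors="coerce")
    paired = df.dropna(subset=["weight_second_g"]).copy()
    paired["daily_weight_change"] = paired["weight_second_g"] - paired["weight_first_g"]
    out = {
        "daily_weight_change": models.fit_lmm(
            paired,
            "daily_weight_change",
            ["age_years", "C(sex)", "weight_first_g", "rainfall_60d_mm", "group_size"],
            ["individual_id", "group_id"],
        ),
        "weight": models.fit_lmm(
            df,
            "weight_first_g",
            ["age_years", "C(sex)", "rainfall_60d_mm", "group_size"],
            ["individual_id", "group_id"],
        ),
    }
    return out


def run_pipeline(config: PipelineConfig, synthetic_config=None) -> PipelineResult:
    """Execute the full analysis and write its artifact files.

    With ``config.synthetic`` set, tables come from the seeded generators;
    ``synthetic_config`` overrides the default generator settings (the seed
    and p-level are always taken from ``config``).
    """
    log: list[str] = [f"pipeline start: seed={config.seed}, p_level={config.p_level}"]
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    weight_frame = None
    if config.synthetic:
        from .synthetic import (
            SyntheticConfig,
            generate_isotope_dataset,
            generate_weight_dataset,
            weights_to_frame,
        )

        if synthetic_config is None:
            synth = SyntheticConfig(seed=config.seed, p_level=config.p_level)
        else:
            synth = dataclasses.replace(
                synthetic_config, seed=config.seed, p_level=config.p_level
            )
        samples, census, attributes, _ = generate_isotope_dataset(synth)
        weights, _ = generate_weight_dataset(synth)
        weight_frame = weights_to_frame(weights)
        _log(log, f"synthetic data: {len(samples)} isotope samples, {len(weights)} weight records")
    else:
        if config.isotope_path is None or config.census_path is None:
            raise ValueError("isotope_path and census_path are required unless synthetic=True")
        samples = read_isotope_table(config.isotope_path)
        census = read_census_table(config.census_path)
        attributes = (
            pd.read_csv(config.attributes_path)
            if config.attributes_path
            else pd.DataFrame(columns=["individual_id", "group_id", "sex", "age_years"])
        )
        if config.weights_path:
            weight_frame = pd.read_csv(config.weights_path)
        _log(log, f"loaded {len(samples)} isotope samples, {len(census)} census records")

    individual_table, group_table = build_rini_table(
        samples,
        census,
        attributes,
        min_samples=config.min_samples,
        p_level=config.p_level,
        n_vertices=config.n_vertices,
        size_threshold=config.size_threshold,
        log=log,
    )

    if individual_table.empty:
        _log(log, "no individual passed the minimum-sample filter; empty result")
        (out_dir / "pipeline.log").write_text("\n".join(log) + "\n")
        return PipelineResult(individual_table, group_table, {}, log, empty=True)

    model_results = fit_rini_models(individual_table, group_table)
    if weight_frame is not None and len(weight_frame):
        model_results.update(fit_weight_models(weight_frame))

    fmt = "%.10g"
    individual_table.to_csv(out_dir / "individual_niche.csv", index=False, float_format=fmt)
    group_table.to_csv(out_dir / "group_niche.csv", index=False, float_format=fmt)
    if model_results:
        pd.concat([r.to_frame().assign(model=name) for name, r in model_results.items()]).to_csv(
            out_dir / "models.csv", index=False, float_format=fmt
        )
        with open(out_dir / "models.json", "w") as fh:
            json.dump(
                {name: r.to_json_dict() for name, r in model_results.items()},
                fh,
                indent=1,
                sort_keys=True,
            )
    _log(log, f"fitted {len(model_results)} model(s); outputs in {out_dir}")
    (out_dir / "pipeline.log").write_text("\n".join(log) + "\n")
    return PipelineResult(individual_table, group_table, model_results, log)
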