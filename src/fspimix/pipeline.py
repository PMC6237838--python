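"""End-to-end analysis pipeline.

Mirrors the experiment's analysis layout at the analysis day (day 21):

* bioturbation responses (L_max, L_med, L_mean, SBR): one main
  PERMANOVA over the five clam ratios (control excluded) per response,
  plus five separate control-vs-ratio contrasts per response — except
  SBR, which has no control contrasts because unstocked aquaria have no
  remobilised sediment-water interface;
* nutrients (NH4-N, NOx-N, PO4-P at day 21): same main + contrast layout;
* a normalised PCA of the per-treatment-per-day mean nutrient vectors.

Every response is analysed univariately through the same distance-based
machinery: Euclidean distances on log(X+1)-transformed values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .metrics import compute_metrics, metrics_table
from .permstats import (
    PCAResult,
    euclidean_distances,
    log1p_transform,
    pca,
    permanova_oneway,
    permanova_pairwise,
)
from .quantify import MODE_CONTROL, MODE_TREATMENT, ProfileImage, quantify_image
from .synthetic import NUTRIENT_COLUMNS, ExperimentDesign

logger = logging.getLogger("fspimix")

ALPHA = 0.05
METRIC_RESPONSES = ("l_max_mm", "l_med_mm", "l_mean_mm")


@dataclass(frozen=True)
class TestOutcome:
    """One cell of the main-test / contrast layout."""

    block: str                  # "bioturbation" or "nutrients"
    response: str
    kind: str                   # "main" or "contrast"
    contrast: str | None        # treatment label for contrasts
    statistic_name: str         # "pseudo-F" or "t"
    statistic: float | None
    df1: int | None
    df2: int | None
    p_perm: float | None
    n_permutations: int | None
    method: str | None
    significant: bool | None    # p < 0.05
    error: str | None = None


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_images(
    directory, design: ExperimentDesign, resolution_mm_per_px: float,
) -> dict[str, ProfileImage]:
    """Read the analysis-day PNG of every aquarium in ``design``.

    Filenames must be ``<aquarium_id>_d<analysis_day>.png``; missing or
    unexpected files are errors (partial bundles signal data problems).
    """
    import imageio.v3 as iio

    directory = Path(directory)
    day = design.analysis_day
    expected = {f"{aq_id}_d{day}.png": aq_id for aq_id, _, _ in design.aquaria}
    present = {p.name for p in directory.iterdir() if p.is_file()
               and not p.name.endswith(".csv")}
    missing = sorted(set(expected) - present)
    if missing:
        raise FileNotFoundError(
            f"missing image(s) for aquaria: "
            f"{[expected[m] for m in missing]}")
    extra = sorted(present - set(expected))
    if extra:
        raise ValueError(f"unexpected file(s) in image directory: {extra}")
    images = {}
    for name, aq_id in expected.items():
        pixels = iio.imread(directory / name)
        images[aq_id] = ProfileImage(
            pixels=np.asarray(pixels)[..., :3],
            resolution_mm_per_px=resolution_mm_per_px,
            aquarium_id=aq_id, day=day,
        )
    logger.info("loaded %d profile images from %s", len(images), directory)
    return images


def load_nutrients(csv_path, design: ExperimentDesign) -> pd.DataFrame:
    """Read and validate the nutrient table against the design."""
    df = pd.read_csv(csv_path)
    required = ["aquarium_id", "treatment", "replicate", "day", *NUTRIENT_COLUMNS]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"nutrient table lacks column(s) {missing_cols}")
    known = {aq_id for aq_id, _, _ in design.aquaria}
    unknown = sorted(set(df["aquarium_id"]) - known)
    if unknown:
        raise ValueError(f"unknown aquarium id(s) in nutrient table: {unknown}")
    for col in NUTRIENT_COLUMNS:
        if (df[col] < 0).any():
            raise ValueError(f"negative concentration in column {col}")
    days = set(design.sampling_days)
    for aq_id in sorted(known):
        have = set(df.loc[df["aquarium_id"] == aq_id, "day"])
        lost = sorted(days - have)
        if lost:
            raise ValueError(f"aquarium {aq_id} is missing day(s) {lost}")
    return df


# ---------------------------------------------------------------------------
# quantification over a whole experiment
# ---------------------------------------------------------------------------

def quantify_experiment(
    images: dict[str, ProfileImage], design: ExperimentDesign,
) -> pd.DataFrame:
    """Quantify every aquarium image into the per-aquarium metrics table.

    Control aquaria use the sediment/luminophore-carpet interface (the
    surface carpet is never remobilised there), stocked aquaria the
    sediment-water interface; SBR is left empty for controls.
    """
    rows = []
    for aq_id, label, rep in design.aquaria:
        treatment = design.treatment(label)
        mode = MODE_CONTROL if treatment.is_control else MODE_TREATMENT
        profile, trace = quantify_image(images[aq_id], mode=mode)
        m = compute_metrics(profile, trace, treatment.is_control,
                            aquarium_id=aq_id, day=design.analysis_day)
        rows.append({
            "aquarium_id": aq_id, "treatment": label,
            "n_rd": treatment.n_rd, "n_rp": treatment.n_rp,
            "replicate": rep, "day": design.analysis_day,
            "l_max_mm": m.l_max_mm, "l_med_mm": m.l_med_mm,
            "l_mean_mm": m.l_mean_mm,
            "sbr_mm": np.nan if m.sbr_mm is None else m.sbr_mm,
        })
    return metrics_table(rows)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def _response_tests(
    block: str,
    values: pd.Series,
    treatments: pd.Series,
    design: ExperimentDesign,
    response: str,
    n_permutations: int,
    seed_stream: np.random.Generator,
    contrasts: bool = True,
) -> list[TestOutcome]:
    """Main ratios test plus (optionally) one control contrast per ratio,
    on one univariate log(X+1)/Euclidean response."""
    control = design.control_label
    out: list[TestOutcome] = []

    def _seed() -> int:
        return int(seed_stream.integers(2 ** 31))

    bivalve = treatments != control
    x = log1p_transform(values.to_numpy(dtype=float)[:, None])
    try:
        dist = euclidean_distances(x[bivalve.to_numpy()])
        res = permanova_oneway(
            dist, treatments[bivalve].to_numpy(), n_permutations, _seed())
        out.append(TestOutcome(
            block=block, response=response, kind="main", contrast=None,
            statistic_name="pseudo-F", statistic=res.pseudo_f,
            df1=res.df_among, df2=res.df_within, p_perm=res.p_perm,
            n_permutations=res.n_permutations, method=res.method,
            significant=res.p_perm < ALPHA,
        ))
    except ValueError as err:
        out.append(TestOutcome(
            block=block, response=response, kind="main", contrast=None,
            statistic_name="pseudo-F", statistic=None, df1=None, df2=None,
            p_perm=None, n_permutations=None, method=None,
            significant=None, error=str(err),
        ))
    if not contrasts:
        return out
    if control is None:
        raise ValueError("design has no control group for contrasts")
    for label in design.treatment_labels:
        sel = (treatments == control) | (treatments == label)
        try:
            dist = euclidean_distances(x[sel.to_numpy()])
            res = permanova_pairwise(
                dist, treatments[sel].to_numpy(), (control, label),
                n_permutations, _seed())
            out.append(TestOutcome(
                block=block, response=response, kind="contrast",
                contrast=label, statistic_name="t", statistic=res.t_statistic,
                df1=1, df2=int(sel.sum()) - 2, p_perm=res.p_perm,
                n_permutations=res.n_permutations, method=res.method,
                significant=res.p_perm < ALPHA,
            ))
        except ValueError as err:
            out.append(TestOutcome(
                block=block, response=response, kind="contrast",
                contrast=label, statistic_name="t", statistic=None,
                df1=None, df2=None, p_perm=None, n_permutations=None,
                method=None, significant=None, error=str(err),
            ))
    return out


def run_bioturbation_tests(
    metrics: pd.DataFrame,
    design: ExperimentDesign,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> list[TestOutcome]:
    """Main test + control contrasts for each L metric; SBR main test only
    (on stocked aquaria — controls carry no SBR value at all)."""
    for col in (*METRIC_RESPONSES, "sbr_mm"):
        if col not in metrics.columns:
            raise ValueError(f"metrics table lacks column {col}")
    stream = np.random.default_rng(seed)
    out: list[TestOutcome] = []
    for response in METRIC_RESPONSES:
        out += _response_tests(
            "bioturbation", metrics[response], metrics["treatment"],
            design, response, n_permutations, stream)
    stocked = metrics["treatment"] != design.control_label
    sub = metrics[stocked]
    out += _response_tests(
        "bioturbation", sub["sbr_mm"], sub["treatment"], design,
        "sbr_mm", n_permutations, stream, contrasts=False)
    return out


def run_nutrient_tests(
    nutrients: pd.DataFrame,
    design: ExperimentDesign,
    analysis_day: int | None = None,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> list[TestOutcome]:
    """Per-nutrient main test + control contrasts at the analysis day."""
    day = design.analysis_day if analysis_day is None else analysis_day
    at_day = nutrients[nutrients["day"] == day]
    if len(at_day) != len(design.aquaria):
        raise ValueError(f"nutrient table does not cover day {day} "
                         f"for every aquarium")
    stream = np.random.default_rng(seed)
    out: list[TestOutcome] = []
    for nutrient in NUTRIENT_COLUMNS:
        out += _response_tests(
            "nutrients", at_day[nutrient], at_day["treatment"],
            design, nutrient, n_permutations, stream)
    return out


def run_nutrient_pca(
    nutrients: pd.DataFrame,
    design: ExperimentDesign,
    per_aquarium: bool = False,
    normalize: bool = True,
) -> tuple[PCAResult, pd.DataFrame]:
    """Normalised PCA of nutrient concentrations.

    Default input points are the per-treatment-per-day mean concentration
    vectors (3 variables); ``per_aquarium=True`` ordinates raw
    aquarium-day points instead.
    """
    if len(design.labels) < 2 or len(design.sampling_days) < 2:
        raise ValueError("PCA needs at least 2 treatments and 2 days")
    if per_aquarium:
        points = nutrients[["treatment", "day", *NUTRIENT_COLUMNS]].copy()
    else:
        points = (nutrients.groupby(["treatment", "day"], sort=True)
                  [list(NUTRIENT_COLUMNS)].mean().reset_index())
    result = pca(points[list(NUTRIENT_COLUMNS)].to_numpy(), normalize=normalize)
    return result, points


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    metrics: pd.DataFrame
    bioturbation_tests: list[TestOutcome]
    nutrient_tests: list[TestOutcome]
    pca_result: PCAResult | None
    pca_points: pd.DataFrame | None
    provenance: dict = field(default_factory=dict)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_full_analysis(
    metrics: pd.DataFrame,
    nutrients: pd.DataFrame,
    design: ExperimentDesign,
    n_permutations: int = 9999,
    seed: int | None = None,
    analysis_day: int | None = None,
) -> AnalysisReport:
    """All tests of the day-21 layout plus the nutrient PCA."""
    bio = run_bioturbation_tests(metrics, design, n_permutations, seed)
    nut = run_nutrient_tests(nutrients, design, analysis_day, n_permutations,
                             None if seed is None else seed + 1)
    pca_result, pca_points = run_nutrient_pca(nutrients, design)
    provenance = {
        "software": f"fspimix {__version__}",
        "seed": seed,
        "n_permutations": n_permutations,
        "analysis_day": design.analysis_day if analysis_day is None
                        else analysis_day,
        "alpha": ALPHA,
    }
    return AnalysisReport(
        metrics=metrics, bioturbation_tests=bio, nutrient_tests=nut,
        pca_result=pca_result, pca_points=pca_points, provenance=provenance,
    )


def tests_frame(report: AnalysisReport) -> pd.DataFrame:
    rows = [dataclasses.asdict(t)
            for t in report.bioturbation_tests + report.nutrient_tests]
    return pd.DataFrame(rows)


def write_report(report: AnalysisReport, out_dir, figures: bool = False) -> list[str]:
    """Serialise the report: metrics.csv, tests.csv, pca_scores.csv,
    pca_loadings.csv and report.json (plus optional figures)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    report.metrics.to_csv(out / "metrics.csv", index=False, float_format="%.6f")
    written.append("metrics.csv")
    tests_frame(report).to_csv(out / "tests.csv", index=False,
                               float_format="%.6f")
    written.append("tests.csv")

    pca_present = report.pca_result is not None
    if pca_present:
        scores = report.pca_points.copy()
        for j in range(report.pca_result.scores.shape[1]):
            scores[f"pc{j + 1}"] = report.pca_result.scores[:, j]
        scores.to_csv(out / "pca_scores.csv", index=False, float_format="%.6f")
        written.append("pca_scores.csv")
        loadings = pd.DataFrame(
            report.pca_result.loadings,
            index=list(NUTRIENT_COLUMNS),
            columns=[f"pc{j + 1}"
                     for j in range(report.pca_result.loadings.shape[1])],
        )
        loadings.to_csv(out / "pca_loadings.csv", float_format="%.6f")
        written.append("pca_loadings.csv")

    payload = {
        "provenance": report.provenance,
        "tests": [dataclasses.asdict(t)
                  for t in report.bioturbation_tests + report.nutrient_tests],
        "pca": ({"explained_fraction":
                 report.pca_result.explained_fraction.tolist(),
                 "normalized": report.pca_result.normalized}
                if pca_present else None),
        "sections": {"metrics": True, "tests": True, "pca": pca_present},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    written.append("report.json")

    if figures:
        _write_figures(report, out)
        written += ["metrics_bars.png", "pca_biplot.png"]
    logger.info("wrote report files %s to %s", written, out)
    return written


def _write_figures(report: AnalysisReport, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 4, figsize=(14, 3.2))
    for ax, col in zip(axes, (*METRIC_RESPONSES, "sbr_mm")):
        stats = report.metrics.groupby("treatment")[col].agg(["mean", "std"])
        stats = stats.dropna()
        ax.bar(stats.index, stats["mean"], yerr=stats["std"], capsize=3)
        ax.set_title(col)
        ax.set_ylabel("mm")
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(out / "metrics_bars.png", dpi=120)
    plt.close(fig)

    if report.pca_result is not None:
        frac = report.pca_result.explained_fraction
        fig, ax = plt.subplots(figsize=(5, 5))
        pts = report.pca_points
        for label, grp in pts.assign(
                pc1=report.pca_result.scores[:, 0],
                pc2=report.pca_result.scores[:, 1]).groupby("treatment"):
            ax.scatter(grp["pc1"], grp["pc2"], label=str(label), s=18)
        for j, var in enumerate(NUTRIENT_COLUMNS):
            ax.annotate(var, (0, 0),
                        xytext=(report.pca_result.loadings[j, 0] * 2,
                                report.pca_result.loadings[j, 1] * 2),
                        arrowprops=dict(arrowstyle="<-", lw=0.8))
        ax.set_xlabel(f"PC1 ({frac[0] * 100:.1f}%)")
        ax.set_ylabel(f"PC2 ({frac[1] * 100:.1f}%)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "pca_biplot.png", dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Read a TOML or YAML run configuration.

    Recognised sections: [design] (ratios, n_replicates, sampling_days,
    analysis_day, include_control), [depth] (n_particles, scale_sd_mm,
    headline), [render] (preset "desk"/"full" or explicit RenderParams
    fields), [nutrients] (headline), [seed] (master).
    """
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix in (".yaml", ".yml"):
        import yaml
        with open(path) as fh:
            return yaml.safe_load(fh)
    raise ValueError(f"unsupported config format {path.suffix!r}")
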