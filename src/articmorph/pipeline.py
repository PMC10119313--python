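"""Cohort pipeline: extraction -> frames -> morphometry -> curvature ->
similarity -> statistics, with report tables.

The report bundle mirrors the four summary tables of a morphometric study of
tarsometatarsal articular surfaces: per-bone size (area/width/height),
width-by-height profiles, signed Gaussian curvature for whole surfaces and
quadrants, and joint curvature-similarity -- each with mean, SD and 95% CI
across the cohort -- plus a statistical report (normality, paired and
one-sample t-tests, three-way ANOVA, Games-Howell post-hocs).

Every random choice is seeded and all outputs are written with stable row
ordering and fixed float formatting, so a rerun with the same seed and
configuration produces byte-identical tables.  Timings go to the run log
only, never into the bundle.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd

from . import mesh_core
from .curvature import principal_curvatures, region_mean_curvature
from .extraction import DEFAULT_THRESHOLDS, extract_articular_surface
from .frames import AnatomicFrame, cuneiform_frame, metatarsal_frame
from .mesh_core import PatchLabel, SurfacePatch, patch_area, read_mesh, write_mesh
from .morphometry import QUADRANTS, max_extents, quadrant_split, width_profile
from .phantoms import JointPhantom, PhantomBone
from .similarity import joint_similarity
from .stats import games_howell, shapiro_wilk, summary_ci, t_test, three_way_anova

__all__ = ["PipelineConfig", "BoneResult", "run_pipeline", "process_bone",
           "analyze_joints", "write_cohort", "read_manifest_joints"]

log = logging.getLogger(__name__)

_CUNEIFORMS = ("medial_cuneiform", "intermediate_cuneiform")
_VARIANTS = {
    "medial_cuneiform": "medial",
    "intermediate_cuneiform": "intermediate",
    "metatarsal1": "MT1",
    "metatarsal2": "MT2",
}


@dataclass
class PipelineConfig:
    """All tunables of the analysis, echoed verbatim into the run log."""

    thresholds: dict = dfield(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    gaussian_radius: float = 10.0  # mm, curvature averaging
    extraction_radius: float = 1.5  # mm, curvature for thresholding
    profile_step: float = 2.0  # mm
    min_n: int | None = None  # heights below this n are dropped (default: half cohort)
    log_base: float = math.e  # base of the similarity log term
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t >= 0 for t in self.thresholds.values()):
            raise ValueError("extraction thresholds must be negative")
        if min(self.gaussian_radius, self.extraction_radius, self.profile_step) <= 0:
            raise ValueError("radii and step must be positive")
        if self.min_n is not None and self.min_n < 1:
            raise ValueError("min_n must be >= 1")

    def to_dict(self) -> dict:
        return {
            "thresholds": dict(self.thresholds),
            "gaussian_radius": self.gaussian_radius,
            "extraction_radius": self.extraction_radius,
            "profile_step": self.profile_step,
            "min_n": self.min_n,
            "log_base": self.log_base,
            "seed": self.seed,
        }


@dataclass
class BoneResult:
    """Everything measured on one bone's analyzed articular surface."""

    specimen: str
    side: str
    joint: str
    bone: str
    patch: SurfacePatch  # analyzed surface as a standalone submesh patch
    source_patch: SurfacePatch  # same surface on (an extension of) the input mesh
    frame: AnatomicFrame
    field: "object"  # CurvatureField on the submesh
    area: float
    width: float
    height: float
    profile: pd.DataFrame
    curvature: dict  # region -> signed Gaussian mean


def _seed_point(mesh, distal_hint: np.ndarray, end: str) -> np.ndarray:
    proj = mesh.vertices @ distal_hint
    idx = int(np.argmax(proj) if end == "distal" else np.argmin(proj))
    return mesh.vertices[idx]


def process_bone(
    mesh,
    bone: str,
    side: str,
    joint: str,
    specimen: str,
    hints: dict,
    config: PipelineConfig,
) -> BoneResult:
    """Run the single-bone chain: extract, frame, measure.

    ``hints`` must carry approximate unit vectors ``dorsal``, ``distal`` and,
    for first metatarsals, ``lateral`` (e.g. the scanner axes).
    """
    threshold = config.thresholds[bone]
    ext_field = principal_curvatures(mesh, config.extraction_radius)
    analyzed_end = "distal" if bone in _CUNEIFORMS else "proximal"
    label = PatchLabel(bone, analyzed_end, side)
    patch = extract_articular_surface(
        mesh, ext_field, threshold,
        seed_point=_seed_point(mesh, hints["distal"], analyzed_end), label=label,
    )
    if bone in _CUNEIFORMS:
        prox = extract_articular_surface(
            mesh, ext_field, threshold,
            seed_point=_seed_point(mesh, hints["distal"], "proximal"),
            label=PatchLabel(bone, "proximal", side),
        )
        frame = cuneiform_frame(
            prox, patch, _VARIANTS[bone], hints["dorsal"], side, bone=bone
        )
    else:
        frame = metatarsal_frame(
            patch, mesh, _VARIANTS[bone], hints["dorsal"], hints.get("lateral"),
            side, bone=bone,
        )

    sub, _, _ = patch.submesh()
    sub_patch = SurfacePatch(sub, np.arange(len(sub.faces)), label=label)
    gauss = principal_curvatures(sub, config.gaussian_radius)
    curv = {"whole": region_mean_curvature(gauss, sub_patch)}
    for name, qp in quadrant_split(sub_patch, frame, strict=False).items():
        curv[name] = region_mean_curvature(gauss, qp) if len(qp) else np.nan

    width, height = max_extents(sub_patch, frame)
    prof = width_profile(sub_patch, frame, step=config.profile_step).table
    return BoneResult(
        specimen=specimen, side=side, joint=joint, bone=bone,
        patch=sub_patch, source_patch=patch, frame=frame, field=gauss,
        area=patch_area(sub_patch), width=width, height=height,
        profile=prof, curvature=curv,
    )


def _phantom_units(joints: list[JointPhantom]):
    for jp in joints:
        for b in (jp.cuneiform, jp.metatarsal):
            yield {
                "specimen": jp.specimen or "S01",
                "side": jp.side,
                "joint": jp.joint,
                "bone": b.bone,
                "mesh": b.mesh,
                "hints": b.hints,
            }


def analyze_joints(
    joints: list[JointPhantom], config: PipelineConfig | None = None
) -> tuple[list[BoneResult], list]:
    """Convenience driver over in-memory joint phantoms.

    Returns bone results plus per-joint similarity results; raises only if
    every specimen fails.
    """
    config = config or PipelineConfig()
    results, failures = [], []
    for unit in _phantom_units(joints):
        try:
            results.append(
                process_bone(
                    unit["mesh"], unit["bone"], unit["side"], unit["joint"],
                    unit["specimen"], unit["hints"], config,
                )
            )
        except Exception as exc:  # noqa: BLE001 - specimen-level isolation
            log.warning("bone failed: %s %s: %s", unit["specimen"], unit["bone"], exc)
            failures.append((unit["specimen"], unit["bone"], str(exc)))
    if not results:
        raise RuntimeError("all specimens failed")
    sims = _pair_similarity(results, config)
    return results, sims


def _pair_similarity(results: list[BoneResult], config: PipelineConfig):
    by_joint: dict[tuple, dict] = {}
    for r in results:
        key = (r.specimen, r.side, r.joint)
        role = "cun" if r.bone in _CUNEIFORMS else "met"
        by_joint.setdefault(key, {})[role] = r
    sims = []
    for (specimen, side, joint), pair in sorted(by_joint.items()):
        if "cun" not in pair or "met" not in pair:
            continue
        c, m = pair["cun"], pair["met"]
        res = joint_similarity(
            c.patch, c.field, c.frame, m.patch, m.field, m.frame,
            joint=joint, log_base=config.log_base,
        )
        for r in res:
            sims.append(
                {
                    "specimen": specimen, "side": side, "joint": joint,
                    "region": r.region, "k_cun": r.k_cun, "k_met": r.k_met,
                    "similarity": r.value,
                }
            )
    return sims


# ---------------------------------------------------------------------------
# report tables


def _summarize(df: pd.DataFrame, value: str, by: list[str]) -> pd.DataFrame:
    rows = []
    for key, grp in df.groupby(by, sort=True):
        vals = grp[value].dropna().to_numpy()
        if len(vals) < 2:
            stat = {"mean": vals.mean() if len(vals) else np.nan, "sd": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan}
        else:
            s = summary_ci(vals)
            stat = {"mean": s.estimate, "sd": s.statistic,
                    "ci_low": s.ci_low, "ci_high": s.ci_high}
        key = key if isinstance(key, tuple) else (key,)
        rows.append({**dict(zip(by, key)), "n": len(vals), **stat})
    return pd.DataFrame(rows)


def build_tables(results: list[BoneResult], sims: list, config: PipelineConfig):
    """Assemble the four report tables and the tidy per-measurement table."""
    size = pd.DataFrame(
        [
            {"specimen": r.specimen, "side": r.side, "joint": r.joint,
             "bone": r.bone, "area": r.area, "width": r.width, "height": r.height}
            for r in results
        ]
    ).sort_values(["bone", "specimen", "side"], ignore_index=True)
    t1 = []
    for metric in ("area", "width", "height"):
        s = _summarize(size, metric, ["bone"])
        s.insert(0, "metric", metric)
        t1.append(s)
    table1 = pd.concat(t1, ignore_index=True)

    prof_rows = []
    for r in results:
        p = r.profile[r.profile["present"]]
        for _, row in p.iterrows():
            prof_rows.append(
                {"specimen": r.specimen, "side": r.side, "bone": r.bone,
                 "height": row["height"], "medial_distance": row["medial_distance"],
                 "lateral_distance": row["lateral_distance"],
                 "total_distance": row["total_distance"]}
            )
    profiles = pd.DataFrame(prof_rows)
    t2 = []
    for metric in ("medial_distance", "lateral_distance", "total_distance"):
        s = _summarize(profiles, metric, ["bone", "height"])
        s.insert(0, "metric", metric)
        t2.append(s)
    table2_full = pd.concat(t2, ignore_index=True)
    n_cohort = size.groupby("bone").size().max()
    min_n = config.min_n if config.min_n is not None else max(1, int(n_cohort // 2))
    table2 = table2_full[table2_full["n"] >= min_n].reset_index(drop=True)

    curv_rows = [
        {"specimen": r.specimen, "side": r.side, "joint": r.joint, "bone": r.bone,
         "region": region, "curvature": k}
        for r in results
        for region, k in r.curvature.items()
    ]
    curv = pd.DataFrame(curv_rows).sort_values(
        ["bone", "region", "specimen", "side"], ignore_index=True
    )
    table3 = _summarize(curv, "curvature", ["bone", "region"])

    simdf = pd.DataFrame(sims)
    table4 = (
        _summarize(simdf, "similarity", ["joint", "region"])
        if len(simdf)
        else pd.DataFrame()
    )
    return {
        "table1_size": table1,
        "table2_profiles": table2,
        "table2_profiles_full": table2_full,
        "table3_curvature": table3,
        "table4_similarity": table4,
        "size_raw": size,
        "profiles_raw": profiles,
        "curvature_raw": curv,
        "similarity_raw": simdf,
    }


def build_stats_report(tables: dict) -> pd.DataFrame:
    """The statistical battery over the cohort tables."""
    rows = []

    def add(context, res):
        rows.append(
            {"context": context, "test": res.test, "estimate": res.estimate,
             "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
             "ci_low": res.ci_low, "ci_high": res.ci_high, "tail": res.tail}
        )

    size, curv, sims = tables["size_raw"], tables["curvature_raw"], tables["similarity_raw"]
    pairs = {"TMT1": ("medial_cuneiform", "metatarsal1"),
             "TMT2": ("intermediate_cuneiform", "metatarsal2")}
    for joint, (cb, mb) in pairs.items():
        for metric in ("area", "width", "height"):
            a = size[size["bone"] == cb].set_index(["specimen", "side"])[metric]
            b = size[size["bone"] == mb].set_index(["specimen", "side"])[metric]
            common = a.index.intersection(b.index)
            if len(common) >= 2:
                add(f"{joint}:{metric}:paired_cun_vs_met",
                    t_test(a.loc[common], paired_with=b.loc[common], mode="paired"))
    whole = curv[curv["region"] == "whole"]
    for bone, grp in whole.groupby("bone"):
        vals = grp["curvature"].dropna()
        if len(vals) >= 3:
            add(f"{bone}:curvature:normality", shapiro_wilk(vals))
        if len(vals) >= 2:
            add(f"{bone}:curvature:vs_zero",
                t_test(vals, mu0=0.0, mode="one_sample_two_tailed"))
    try:
        an = three_way_anova(whole.rename(columns={"curvature": "value"}),
                             "value", ("bone", "specimen", "side"))
        for factor in an.index[:-1]:
            rows.append({"context": "curvature:anova", "test": f"anova_{factor}",
                         "estimate": np.nan, "statistic": an.loc[factor, "F"],
                         "df": an.loc[factor, "df"],
                         "p_value": an.loc[factor, "PR(>F)"],
                         "ci_low": np.nan, "ci_high": np.nan, "tail": "two-sided"})
    except ValueError as exc:
        log.warning("curvature ANOVA skipped: %s", exc)
    for bone, grp in curv[curv["region"] != "whole"].groupby("bone"):
        groups, labels = [], []
        for region, g in grp.groupby("region"):
            vals = g["curvature"].dropna().to_numpy()
            if len(vals) >= 2:
                groups.append(vals)
                labels.append(region)
        if len(groups) >= 2:
            gh = games_howell(groups, labels)
            for _, r in gh.iterrows():
                rows.append({"context": f"{bone}:curvature:games_howell",
                             "test": f"{r['group_a']}|{r['group_b']}",
                             "estimate": r["mean_diff"], "statistic": r["t"],
                             "df": r["df"], "p_value": r["p_value"],
                             "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                             "tail": "two-sided"})
    if len(sims):
        for (joint, region), grp in sims.groupby(["joint", "region"]):
            vals = grp["similarity"].dropna()
            if len(vals) < 2:
                continue
            add(f"{joint}:{region}:similarity:vs_plus1",
                t_test(vals, mu0=1.0, mode="one_sample_two_tailed"))
            add(f"{joint}:{region}:similarity:vs_minus1",
                t_test(vals, mu0=-1.0, mode="one_sample_two_tailed"))
            add(f"{joint}:{region}:similarity:vs_zero_one_tailed",
                t_test(vals, mu0=0.0, mode="one_sample_one_tailed"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk interface


def write_cohort(joints: list[JointPhantom], outdir: str | Path) -> Path:
    """Write phantom meshes plus a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for jp in joints:
        for b in (jp.cuneiform, jp.metatarsal):
            name = f"{jp.specimen}_{jp.side}_{b.bone}.ply"
            write_mesh(b.mesh, outdir / name)
            row = {
                "specimen": jp.specimen, "side": jp.side, "joint": jp.joint,
                "bone": b.bone, "path": name,
            }
            for hint in ("dorsal", "lateral", "distal"):
                for ax, v in zip("xyz", b.hints[hint]):
                    row[f"hint_{hint}_{ax}"] = v
            row["truth_curvature"] = b.truth_curvature[b.analyzed_end]
            row["truth_width"], row["truth_height"] = b.truth_extents[b.analyzed_end]
            row["truth_similarity"] = jp.truth_similarity
            rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest_joints(manifest: str | Path) -> list[dict]:
    """Rows of a cohort manifest as processing units (meshes loaded lazily)."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    units = []
    for _, row in df.iterrows():
        hints = {}
        for hint in ("dorsal", "lateral", "distal"):
            cols = [f"hint_{hint}_{ax}" for ax in "xyz"]
            if all(c in row for c in cols):
                hints[hint] = np.array([row[c] for c in cols], dtype=float)
        units.append(
            {"specimen": row["specimen"], "side": row["side"],
             "joint": row.get("joint", ""), "bone": row["bone"],
             "path": manifest.parent / row["path"], "hints": hints}
        )
    return units


def _write_bundle(tables: dict, stats_report: pd.DataFrame, config: PipelineConfig,
                  outdir: Path, timings: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    order = ["table1_size", "table2_profiles", "table2_profiles_full",
             "table3_curvature", "table4_similarity",
             "size_raw", "profiles_raw", "curvature_raw", "similarity_raw"]
    for name in order:
        tables[name].to_csv(outdir / f"{name}.csv", index=False, float_format="%.6f")
    stats_report.to_csv(outdir / "stats_report.csv", index=False, float_format="%.6g")
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    with open(outdir / "run.log", "w") as fh:
        fh.write("articmorph pipeline run\n")
        fh.write(json.dumps(config.to_dict(), sort_keys=True) + "\n")
        for stage, dt in timings.items():
            fh.write(f"{stage}: {dt:.2f} s\n")


def run_pipeline(
    manifest: str | Path | None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    joints: list[JointPhantom] | None = None,
) -> dict:
    """Analyze a cohort (from a manifest CSV or in-memory phantoms).

    Per-specimen failures are logged and excluded; the run fails only when
    every specimen fails.  Returns the dict of report tables (plus
    ``stats_report``); when ``outdir`` is given the byte-stable bundle is
    written there.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    results, failures = [], []
    if joints is not None:
        units = list(_phantom_units(joints))
    else:
        units = read_manifest_joints(manifest)
    for unit in units:
        t1 = time.perf_counter()
        try:
            mesh = unit.get("mesh")
            if mesh is None:
                mesh = read_mesh(unit["path"])
            results.append(
                process_bone(mesh, unit["bone"], unit["side"], unit["joint"],
                             unit["specimen"], unit["hints"], config)
            )
        except Exception as exc:  # noqa: BLE001
            log.warning("specimen %s bone %s failed: %s",
                        unit["specimen"], unit["bone"], exc)
            failures.append({**{k: unit[k] for k in ("specimen", "side", "bone")},
                             "error": str(exc)})
        timings[f"{unit['specimen']}:{unit['bone']}"] = time.perf_counter() - t1
    if not results:
        raise RuntimeError("pipeline failed: no specimen could be processed")
    sims = _pair_similarity(results, config)
    tables = build_tables(results, sims, config)
    stats_report = build_stats_report(tables)
    timings["total"] = time.perf_counter() - t0
    if outdir is not None:
        _write_bundle(tables, stats_report, config, Path(outdir), timings)
        if failures:
            pd.DataFrame(failures).to_csv(Path(outdir) / "failures.csv", index=False)
    tables["stats_report"] = stats_report
    tables["_results"] = results
    tables["_failures"] = failures
    return tables
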