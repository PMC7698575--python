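"""End-to-end orchestration: quantify -> features -> statistics -> tables.

The pipeline turns a study (synthetic, or a directory of photographs
listed in a design CSV) into:

- a per-image records table (counts, fractions, SDD),
- a per-treatment summary table (N, TL, W, pixels, SDD, % per view),
- two-way ANOSIM on per-fish yellow fractions (treatment and replicate
  factors) with Bonferroni pairwise post-hocs,
- a Mantel test between pigmentation distances (Manhattan, on the
  per-fish frontal/lateral fraction 2-vector) and dietary carotenoid
  distances (Euclidean, on the scalar concentration),
- one-way ANOVA + Tukey letters for total length and weight,
- overlay and per-treatment mean-image composites.

A run is a pure function of (inputs, config, seed): rerunning with the
same configuration produces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composite import overlay
from .imaging import MaskedImage, load_image
from .permstats import (
    anosim_pairwise,
    anosim_twoway,
    anova_tukey,
    distance_matrix,
    mantel,
)
from .pigment import (
    SEABREAM_YELLOW,
    ColorRange,
    derive_color_range,
    perturb_range,
    quantify,
    sample_pixels,
    yellow_mask,
)
from .synthdata import StudyDesign, SyntheticStudy, default_design, generate_study

logger = logging.getLogger(__name__)

__all__ = [
    "quantify_study",
    "fish_features",
    "pigment_statistics",
    "summary_table",
    "sensitivity_analysis",
    "derive_range_from_study",
    "run_pipeline",
]

RECORD_COLUMNS = [
    "image_id",
    "fish_id",
    "treatment",
    "tank",
    "view",
    "yellow_count",
    "total_foreground",
    "yellow_fraction",
    "sdd",
]


def quantify_study(
    images: Iterable[tuple[pd.Series, MaskedImage]],
    color_range: ColorRange = SEABREAM_YELLOW,
    sdd_method: str = "centroid",
) -> pd.DataFrame:
    """Quantify every image of a study into a records table.

    ``images`` yields (metadata row, MaskedImage) pairs, as produced by
    :meth:`SyntheticStudy.iter_images` or :func:`iter_image_set`.
    """
    rows = []
    for meta, img in images:
        rec = quantify(
            img,
            color_range,
            fish_id=meta["fish_id"],
            treatment=meta["treatment"],
            tank=str(meta["tank"]),
            sdd_method=sdd_method,
        )
        row = {c: getattr(rec, c) for c in RECORD_COLUMNS}
        if "replicate" in meta:
            row["replicate"] = meta["replicate"]
        if "carotenoid" in meta:
            row["carotenoid"] = meta["carotenoid"]
        rows.append(row)
    return pd.DataFrame(rows)


def fish_features(records: pd.DataFrame) -> pd.DataFrame:
    """Per-fish feature table: one row per fish, one yellow-fraction column per view."""
    wide = records.pivot_table(
        index="fish_id", columns="view", values="yellow_fraction", aggfunc="mean"
    )
    meta_cols = [
        c for c in ("treatment", "tank", "replicate", "carotenoid") if c in records
    ]
    meta = records.groupby("fish_id")[meta_cols].first()
    out = meta.join(wide).reset_index()
    return out


def pigment_statistics(
    features: pd.DataFrame,
    views: tuple[str, ...] = ("frontal", "lateral"),
    n_perm_treatment: int = 999,
    n_perm_replicate: int = 999,
    n_perm_mantel: int = 9999,
    seed: int = 0,
    pairwise: bool = True,
) -> dict:
    """Two-way ANOSIM, pairwise post-hocs and the diet Mantel test."""
    view_cols = [v for v in views if v in features]
    X = features.set_index("fish_id")[view_cols]
    dm = distance_matrix(X, metric="manhattan")
    keep = features.set_index("fish_id").loc[list(dm.labels)]

    two = anosim_twoway(
        dm,
        keep["treatment"].to_numpy(),
        keep["replicate"].to_numpy(),
        n_perm=n_perm_treatment,
        n_perm_b=n_perm_replicate,
        seed=seed,
    )
    out: dict = {
        "n_fish": int(dm.n),
        "seed": int(seed),
        "anosim": {
            "metric": "manhattan",
            "treatment": {
                "R": two.factor_a.R,
                "p": two.factor_a.p,
                "n_permutations": two.factor_a.n_permutations,
            },
            "replicate": {
                "R": two.factor_b.R,
                "p": two.factor_b.p,
                "n_permutations": two.factor_b.n_permutations,
            },
        },
    }
    if pairwise:
        pw = anosim_pairwise(
            dm, keep["treatment"].to_numpy(), n_perm=n_perm_treatment, seed=seed + 1
        )
        out["anosim"]["pairwise"] = pw

    if "carotenoid" in keep:
        dm_diet = distance_matrix(
            keep[["carotenoid"]], metric="euclidean", labels=list(dm.labels)
        )
        mres = mantel(
            dm, dm_diet, correlation="spearman", n_perm=n_perm_mantel, seed=seed + 2
        )
        out["mantel"] = {
            "r": mres.r,
            "p": mres.p,
            "n_permutations": mres.n_permutations,
            "correlation": mres.correlation,
        }
    return out


def growth_statistics(fish: pd.DataFrame, alpha: float = 0.05) -> dict:
    """One-way ANOVA with Tukey letters for TL and W across treatments."""
    out = {}
    for trait in ("TL", "W"):
        if trait not in fish:
            continue
        res = anova_tukey(fish[trait].to_numpy(), fish["treatment"].to_numpy(), alpha)
        out[trait] = {
            "F": res.F,
            "p": res.p,
            "df": [res.df_between, res.df_within],
            "letters": res.letters,
        }
    return out


def summary_table(records: pd.DataFrame, fish: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-treatment mean +/- SD summary in the layout of the study's Table.

    Columns per view: mean pixel count, SDD (images with undefined SDD
    are dropped and logged) and % of foreground. TL/W summaries are
    included when a fish table is supplied.
    """
    rows = []
    for treatment, grp in records.groupby("treatment", sort=False):
        row: dict = {"treatment": treatment, "N": int(grp["fish_id"].nunique())}
        if fish is not None:
            f = fish[fish["treatment"] == treatment]
            for trait in ("TL", "W"):
                if trait in f:
                    row[f"{trait}_mean"] = f[trait].mean()
                    row[f"{trait}_sd"] = f[trait].std(ddof=1)
        for view, sub in grp.groupby("view"):
            n_undef = int(sub["sdd"].isna().sum())
            if n_undef:
                logger.warning(
                    "%s/%s: %d image(s) with undefined SDD dropped from SDD summary",
                    treatment, view, n_undef,
                )
            row[f"{view}_pixels_mean"] = sub["yellow_count"].mean()
            row[f"{view}_pixels_sd"] = sub["yellow_count"].std(ddof=1)
            row[f"{view}_sdd_mean"] = sub["sdd"].mean()  # NaN-skipping
            row[f"{view}_sdd_sd"] = sub["sdd"].std(ddof=1)
            row[f"{view}_pct_mean"] = 100 * sub["yellow_fraction"].mean()
            row[f"{view}_pct_sd"] = 100 * sub["yellow_fraction"].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def treatment_ranking(records: pd.DataFrame, view: str) -> list[str]:
    """Treatments ordered by decreasing mean yellow fraction in a view."""
    means = (
        records[records["view"] == view]
        .groupby("treatment")["yellow_fraction"]
        .mean()
        .sort_values(ascending=False, kind="stable")
    )
    return list(means.index)


def sensitivity_analysis(
    study: SyntheticStudy,
    base_range: ColorRange = SEABREAM_YELLOW,
    pct: float = 5.0,
    sdd_method: str = "centroid",
) -> dict:
    """Quantify under the nominal, expanded and shrunk boxes; compare rankings."""
    variants = {
        "base": base_range,
        "expand": perturb_range(base_range, pct, "expand"),
        "shrink": perturb_range(base_range, pct, "shrink"),
    }
    rankings: dict[str, dict[str, list[str]]] = {}
    counts = {}
    for name, rng_box in variants.items():
        rec = quantify_study(study.iter_images(), rng_box, sdd_method)
        rankings[name] = {
            v: treatment_ranking(rec, v) for v in study.design.views
        }
        counts[name] = int(rec["yellow_count"].sum())
    stable = all(
        rankings["base"][v] == rankings[name][v]
        for name in ("expand", "shrink")
        for v in study.design.views
    )
    return {
        "pct": pct,
        "ranges": {k: v.as_flat() for k, v in variants.items()},
        "total_counts": counts,
        "rankings": rankings,
        "rankings_identical": stable,
    }


def derive_range_from_study(
    study: SyntheticStudy,
    n_images_per_tank: int = 3,
    n_pixels_per_image: int = 5,
    seed: int = 0,
    view: str = "frontal",
) -> ColorRange:
    """Reproduce the sampling protocol on a synthetic study.

    For each tank, ``n_pixels_per_image`` yellow pixels are sampled from
    ``n_images_per_tank`` images (frontal view by default) and the box is
    the channelwise min/max over all samples.
    """
    rng = np.random.default_rng(seed)
    samples = []
    img_table = study.images
    for tank, grp in img_table[img_table["view"] == view].groupby("tank"):
        chosen = grp[grp["true_count"] > 0].head(n_images_per_tank)
        for _, row in chosen.iterrows():
            img = study.render_image(row)
            ym = yellow_mask(img, SEABREAM_YELLOW)
            if not ym.any():
                continue
            for _, _, rgb in sample_pixels(img, ym, n_pixels_per_image, rng):
                samples.append(rgb)
    return derive_color_range(samples)


# ---------------------------------------------------------------------------
# image-set input


def iter_image_set(
    design: pd.DataFrame,
    root: Path,
    background_policy: str = "alpha",
    **load_kwargs,
) -> Iterator[tuple[pd.Series, MaskedImage]]:
    """Load the images listed in a design table; failures are logged and skipped."""
    for _, row in design.iterrows():
        path = root / row["image_path"]
        try:
            img = load_image(
                path,
                background_policy,
                view=row["view"],
                image_id=row.get("image_id", path.stem),
                **load_kwargs,
            )
        except Exception as exc:  # noqa: BLE001 - any unreadable image is reported
            logger.warning("skipping %s: %s", path, exc)
            continue
        yield row, img


# ---------------------------------------------------------------------------
# config-driven run


DEFAULT_CONFIG = {
    "mode": "synthetic",
    "seed": 0,
    "image_size": [256, 256],
    "tanks_per_treatment": 3,
    "fish_per_tank": 18,
    "range": "seabream",  # "seabream" | "derive" | [R_lo, R_hi, G_lo, G_hi, B_lo, B_hi]
    "perturb_pct": 0.0,
    "perturb_mode": "expand",
    "sdd_method": "centroid",
    "n_perm_anosim": 999,
    "n_perm_mantel": 9999,
    "write_images": False,
    "overlays_per_group": 1,
    "mean_images": True,
    "sensitivity": False,
}


def _resolve_range(cfg: dict, study: SyntheticStudy | None) -> ColorRange:
    choice = cfg.get("range", "seabream")
    if choice == "seabream":
        box = SEABREAM_YELLOW
    elif choice == "derive":
        if study is None:
            raise ValueError("range 'derive' requires a synthetic study")
        box = derive_range_from_study(study, seed=cfg["seed"])
    else:
        box = ColorRange.from_flat(choice)
    pct = float(cfg.get("perturb_pct", 0) or 0)
    if pct:
        box = perturb_range(box, pct, cfg.get("perturb_mode", "expand"))
    return box


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Execute a full run from a config mapping (or YAML path).

    Writes records.csv, summary.csv, pairwise.csv, stats.json, composites
    and a manifest under ``outdir``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setLevel(logging.WARNING)
    logging.getLogger("fishpigment").addHandler(log_handler)
    try:
        return _run(cfg, outdir)
    finally:
        logging.getLogger("fishpigment").removeHandler(log_handler)
        log_handler.close()


def _run(cfg: dict, outdir: Path) -> Path:
    seed = int(cfg["seed"])
    if cfg["mode"] == "synthetic":
        treatments = cfg.get("treatments")
        design = StudyDesign(
            treatments=[tuple(t) for t in treatments]
            if treatments
            else default_design().treatments,
            tanks_per_treatment=int(cfg["tanks_per_treatment"]),
            fish_per_tank=int(cfg["fish_per_tank"]),
            image_size=tuple(cfg["image_size"]),
            seed=seed,
        )
        study = generate_study(design)
        fish = study.fish
        if cfg.get("write_images"):
            study.write(outdir / "synthetic", write_images=True)
        box = _resolve_range(cfg, study)
        records = quantify_study(study.iter_images(), box, cfg["sdd_method"])
        image_source = study.iter_images
    elif cfg["mode"] == "images":
        root = Path(cfg["image_root"])
        design_df = pd.read_csv(cfg["design_csv"])
        fish = design_df.drop_duplicates("fish_id")
        box = _resolve_range(cfg, None)
        loader = lambda: iter_image_set(  # noqa: E731
            design_df, root, cfg.get("background_policy", "alpha")
        )
        records = quantify_study(loader(), box, cfg["sdd_method"])
        study = None
        image_source = loader
    else:
        raise ValueError(f"unknown mode {cfg['mode']!r}")

    if records.empty:
        raise ValueError("no image could be quantified")

    records = records.sort_values("image_id", kind="stable").reset_index(drop=True)
    records.to_csv(outdir / "records.csv", index=False)

    features = fish_features(records)
    summary = summary_table(records, fish)
    summary.to_csv(outdir / "summary.csv", index=False)

    stats = pigment_statistics(
        features,
        n_perm_treatment=int(cfg["n_perm_anosim"]),
        n_perm_replicate=int(cfg["n_perm_anosim"]),
        n_perm_mantel=int(cfg["n_perm_mantel"]),
        seed=seed,
    )
    pw = stats["anosim"].pop("pairwise", None)
    if pw is not None:
        pw.to_csv(outdir / "pairwise.csv", index=False)
    if fish is not None and "TL" in fish:
        stats["growth"] = growth_statistics(fish)
    stats["color_range"] = list(box.as_flat())
    stats["sdd_method"] = cfg["sdd_method"]

    if cfg.get("sensitivity") and study is not None:
        sens = sensitivity_analysis(study, box)
        stats["sensitivity"] = {
            k: sens[k] for k in ("pct", "total_counts", "rankings_identical")
        }
        with open(outdir / "sensitivity.json", "w") as fh:
            json.dump(sens, fh, indent=2, sort_keys=True, default=str)

    with open(outdir / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)

    if cfg.get("mean_images") or cfg.get("overlays_per_group"):
        _write_composites(image_source(), box, outdir, int(cfg["overlays_per_group"]))

    manifest = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "n_images": int(len(records)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outdir


def _write_composites(images, box: ColorRange, outdir: Path, overlays_per_group: int):
    """Stream images once, writing example overlays and mean images."""
    from PIL import Image

    comp_dir = outdir / "composites"
    comp_dir.mkdir(exist_ok=True)
    acc: dict[tuple, list] = {}
    n_overlaid: dict[tuple, int] = {}
    for meta, img in images:
        key = (meta["treatment"], meta["view"])
        ym = yellow_mask(img, box)
        ov = overlay(img, ym)
        filled = ov.pixels.astype(float).copy()
        filled[~ov.mask] = 255.0
        if key not in acc:
            acc[key] = [np.zeros_like(filled), 0]
        acc[key][0] += filled
        acc[key][1] += 1
        if n_overlaid.get(key, 0) < overlays_per_group:
            Image.fromarray(ov.pixels).save(
                comp_dir / f"overlay_{meta['image_id']}.png"
            )
            n_overlaid[key] = n_overlaid.get(key, 0) + 1
    for (treatment, view), (total, n) in acc.items():
        mean = np.clip(np.floor(total / n + 0.5), 0, 255).astype(np.uint8)
        Image.fromarray(mean).save(comp_dir / f"{treatment}_{view}_mean.png")


def analyze_default_study(
    seed: int = 0,
    image_size: tuple[int, int] = (256, 256),
    n_perm_treatment: int = 1999,
    n_perm_replicate: int = 999,
    n_perm_mantel: int = 9999,
    sdd_method: str = "centroid",
    pairwise: bool = False,
) -> dict:
    """Generate, quantify and test one default synthetic study.

    Returns the records/summary tables plus the ANOSIM/Mantel/ANOVA
    results for the 9-treatment x 3-tank x 18-fish, two-view design.
    """
    study = generate_study(default_design(seed=seed, image_size=image_size))
    records = quantify_study(study.iter_images(), SEABREAM_YELLOW, sdd_method)
    features = fish_features(records)
    stats = pigment_statistics(
        features,
        n_perm_treatment=n_perm_treatment,
        n_perm_replicate=n_perm_replicate,
        n_perm_mantel=n_perm_mantel,
        seed=seed,
        pairwise=pairwise,
    )
    return {
        "study": study,
        "records": records,
        "features": features,
        "summary": summary_table(records, study.fish),
        "stats": stats,
        "growth": growth_statistics(study.fish),
        "frontal_ranking": treatment_ranking(records, "frontal"),
    }
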