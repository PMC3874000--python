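"""End-to-end orchestration: simulate, quantify, summarize.

Two pipelines tie the stages together the way the underlying tissue-microarray
study was run:

* :func:`run_dab_pipeline` — from a manifest of brightfield core images and
  labels to per-core quantification, per-marker group statistics, ROC tables
  and two-marker logistic combinations.  Quantification is blind by design: it
  sees only image paths and core ids, never the label columns.
* :func:`run_coloc_pipeline` — from a manifest of fluorescence stacks with
  matched-pair / relapse labels to per-stack Pearson coefficients and the
  paired group comparison.

All tabular outputs are CSV with frozen column orders; every run writes a
manifest JSON with the config hash and seed so runs are exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import coloc as coloc_mod
from . import diagnostics as diag
from . import stats as cstats
from .particles import CoreImage, QuantConfig, quantify_core
from .synthetic import (
    CohortSpec,
    CoreSpec,
    FluorSpec,
    generate_cohort,
    generate_core_image,
    generate_fluorescence_stack,
)

logger = logging.getLogger(__name__)

QUANT_COLUMNS = [
    "core_id",
    "count",
    "total_area",
    "average_size",
    "area_fraction",
    "tissue_area",
    "normalized_signal",
]

__all__ = [
    "RunConfig",
    "run_dab_pipeline",
    "run_coloc_pipeline",
    "simulate_dab_dataset",
    "simulate_coloc_dataset",
]


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run.

    Serializes losslessly to/from YAML; the SHA-256 of the canonical YAML is
    recorded in every run manifest.
    """

    manifest: str = "manifest.csv"
    output_dir: str = "results"
    threshold_method: str = "multiotsu_dark"  # or "otsu_dark" / "fixed"
    threshold_lo: int = 0
    threshold_hi: int = 0
    gray_mode: str = "unweighted"
    connectivity: int = 8
    size_min: float = 0.5
    size_max: float = float("inf")
    circ_min: float = 0.0
    circ_max: float = 1.0
    probit_mode: str = "proportion"
    mask_mode: str = "either_above"
    seed: int = 0
    log_level: str = "INFO"

    def quant_config(self) -> QuantConfig:
        if self.threshold_method == "fixed":
            dab = ("fixed", self.threshold_lo, self.threshold_hi)
        else:
            dab = (self.threshold_method,)
        return QuantConfig(
            gray_mode=self.gray_mode,
            dab_threshold=dab,
            connectivity=self.connectivity,
            size_min=self.size_min,
            size_max=self.size_max,
            circ_min=self.circ_min,
            circ_max=self.circ_max,
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def _quantify_manifest(paths: pd.DataFrame, qconf: QuantConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Quantify every image in a (core_id, image_path) frame.

    Deliberately takes only ids and paths — label columns never reach the
    quantification stage.  Unreadable images are skipped with a logged reason.
    """
    rows, skipped = [], []
    for core_id, path in paths.itertuples(index=False):
        t0 = time.perf_counter()
        try:
            px = np.asarray(iio.imread(path))
        except Exception as exc:  # noqa: BLE001 - any unreadable image is a skip
            logger.warning("skipping core %s: %s", core_id, exc)
            skipped.append(dict(core_id=str(core_id), reason=str(exc)))
            continue
        if px.ndim == 3 and px.shape[2] == 4:
            px = px[:, :, :3]
        img = CoreImage(pixels=px, bit_depth=8 if px.dtype == np.uint8 else 16,
                        core_id=str(core_id))
        res = quantify_core(img, qconf)
        logger.info("core %s quantified in %.3fs", core_id, time.perf_counter() - t0)
        rows.append({c: getattr(res, c) for c in QUANT_COLUMNS})
    return pd.DataFrame(rows, columns=QUANT_COLUMNS), skipped


def run_dab_pipeline(config: RunConfig) -> dict:
    """Run the brightfield cohort analysis end to end.

    The manifest CSV must hold ``core_id,image_path,marker_name,diagnosis``
    and may hold ``sample_id`` (physical core shared across markers),
    ``gleason`` and ``relapse``.  Writes ``quant.csv``, ``cohort.csv``,
    ``group_stats.csv``, ``roc_points.csv``, ``roc_summary.csv``,
    ``logistic_pairs.csv`` and ``run_manifest.json`` to the output directory
    and returns the tables in a dict.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(config.manifest, dtype={"core_id": str})

    quant, skipped = _quantify_manifest(
        manifest[["core_id", "image_path"]], config.quant_config()
    )

    cohort = quant.merge(
        manifest.drop(columns=["image_path"]), on="core_id", how="inner"
    )
    for col in ("gleason", "relapse"):
        if col not in cohort:
            cohort[col] = "NA"

    stats_rows, roc_point_rows, roc_summary_rows = [], [], []
    for marker, sub in sorted(cohort.groupby("marker_name")):
        ben = sub.loc[sub.diagnosis == "benign", "area_fraction"].to_numpy()
        mal = sub.loc[sub.diagnosis == "malignant", "area_fraction"].to_numpy()
        if ben.size == 0 or mal.size == 0:
            logger.warning("marker %s: one diagnosis group empty; stats skipped", marker)
            continue
        u, p = cstats.mann_whitney_u(ben, mal, method="normal_approx")
        fold = cstats.fold_change(ben, mal, method="mean_ratio")
        fold_auc = cstats.fold_change(ben, mal, method="mountain_auc_ratio")
        for grp, vals in (("benign", ben), ("malignant", mal)):
            stats_rows.append(
                dict(
                    marker=marker,
                    group=grp,
                    n=vals.size,
                    mean=vals.mean(),
                    se=vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0,
                    fold_mean_ratio=round(fold, 1),
                    fold_mountain_auc=round(fold_auc, 1),
                    U=u,
                    p=p,
                )
            )
        scores = diag.probit_transform(
            sub["area_fraction"].to_numpy(), mode=config.probit_mode
        )
        labels = (sub["diagnosis"] == "malignant").astype(int).to_numpy()
        roc = diag.empirical_roc(scores, labels)
        a, b, auc_bn = diag.binormal_roc(scores, labels)
        for crit, sens, fpr, lrp, lrm in roc.operating_points:
            roc_point_rows.append(
                dict(marker=marker, criterion=crit, sensitivity=sens,
                     one_minus_specificity=fpr, lr_plus=lrp, lr_minus=lrm)
            )
        roc_summary_rows.append(
            dict(marker=marker, auc_empirical=roc.auc_empirical,
                 auc_binormal=auc_bn, binormal_a=a, binormal_b=b)
        )

    # two-marker logistic combinations on samples quantified for both markers;
    # the manifest's sample_id ties together sections of one physical core
    # stained for different markers (falls back to core_id)
    logit_rows = []
    key = "sample_id" if "sample_id" in cohort else "core_id"
    wide = cohort.pivot_table(
        index=[key, "diagnosis"], columns="marker_name",
        values="area_fraction", aggfunc="mean",
    ).reset_index()
    markers = sorted(cohort["marker_name"].unique())
    for m1, m2 in combinations(markers, 2):
        if m1 not in wide or m2 not in wide:
            continue
        both = wide.dropna(subset=[m1, m2])
        y = (both["diagnosis"] == "malignant").astype(int).to_numpy()
        if both.shape[0] < 4 or y.min() == y.max():
            continue
        model = diag.fit_logistic_pair(
            both[m1].to_numpy(), both[m2].to_numpy(), y
        )
        logit_rows.append(
            dict(marker_pair=f"{m1}+{m2}", beta0=model.beta0, beta1=model.beta1,
                 beta2=model.beta2, pct_correct=model.pct_correct,
                 separation_flag=model.separation_flag, n_used=model.n_used)
        )

    tables = dict(
        quant=quant,
        cohort=cohort,
        group_stats=pd.DataFrame(stats_rows),
        roc_points=pd.DataFrame(roc_point_rows),
        roc_summary=pd.DataFrame(roc_summary_rows),
        logistic_pairs=pd.DataFrame(logit_rows),
    )
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    run_manifest = dict(
        config_sha256=config.digest(),
        seed=config.seed,
        n_manifest=int(manifest.shape[0]),
        n_usable=int(quant.shape[0]),
        skipped=skipped,
    )
    (outdir / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True)
    )
    tables["run_manifest"] = run_manifest
    return tables


def run_coloc_pipeline(config: RunConfig, channel_pair: tuple[str, str] = ("FITC", "Cy3")) -> dict:
    """Run the fluorescence colocalization analysis end to end.

    The manifest CSV must hold ``stack_path,core_id,pair_id,relapse,channels``
    (``channels`` is a ';'-separated name list matching the TIFF's first
    axis).  Every ``pair_id`` must appear exactly once with relapse=yes and
    once with relapse=no; unmatched ids raise.  Writes ``coloc.csv`` and
    ``coloc_summary.json``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(config.manifest, dtype={"core_id": str, "pair_id": str})

    counts = manifest.groupby(["pair_id", "relapse"]).size().unstack(fill_value=0)
    bad = [
        str(pid)
        for pid, row in counts.iterrows()
        if row.get("yes", 0) != 1 or row.get("no", 0) != 1
    ]
    if bad:
        raise ValueError(f"unmatched pair ids (need one relapse=yes and one =no): {bad}")

    rows = []
    for rec in manifest.itertuples(index=False):
        arr = tifffile.imread(rec.stack_path)
        names = str(rec.channels).split(";")
        if arr.shape[0] != len(names):
            raise ValueError(
                f"stack {rec.stack_path}: {arr.shape[0]} channels, "
                f"{len(names)} names"
            )
        chans = {n: arr[i] for i, n in enumerate(names)}
        a = coloc_mod.max_project(chans[channel_pair[0]])
        b = coloc_mod.max_project(chans[channel_pair[1]])
        mask = coloc_mod.coloc_mask(a, b, mode=config.mask_mode)
        res = coloc_mod.pearson_coloc(
            a, b, mask, channel_pair=channel_pair, mask_mode=config.mask_mode
        )
        rows.append(
            dict(core_id=rec.core_id, pair_id=rec.pair_id,
                 channel_pair=f"{channel_pair[0]}/{channel_pair[1]}",
                 r=res.pearson_r, n_pixels=res.n_pixels_used,
                 mask_mode=res.mask_mode, relapse=rec.relapse)
        )
    coloc_df = pd.DataFrame(rows)
    pairs = []
    for pid, sub in sorted(coloc_df.groupby("pair_id")):
        r_non = float(sub.loc[sub.relapse == "no", "r"].iloc[0])
        r_rel = float(sub.loc[sub.relapse == "yes", "r"].iloc[0])
        pairs.append((r_non, r_rel))
    summary = coloc_mod.compare_coloc_groups(pairs)
    summary["config_sha256"] = config.digest()
    summary["seed"] = config.seed

    coloc_df.to_csv(outdir / "coloc.csv", index=False)
    (outdir / "coloc_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    return dict(coloc=coloc_df, summary=summary)


def simulate_dab_dataset(
    outdir: str | Path,
    n_benign: int = 10,
    n_malignant: int = 10,
    cohort_spec: CohortSpec | None = None,
    markers: tuple[str, ...] = ("synthetic",),
    image_size: int = 256,
    tissue_fraction: float = 0.5,
    noise_sd: float = 0.0,
    blob_count: int = 12,
    seed: int = 0,
) -> Path:
    """Write a synthetic brightfield dataset: core PNGs, ground-truth sidecar
    CSV and a pipeline manifest.  Per-core true stained fractions are drawn
    from the cohort generator (area-fraction percent / 100), so the cohort's
    group structure carries through to the images.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = cohort_spec or CohortSpec()
    manifest_rows, truth_rows = [], []
    for mi, marker in enumerate(markers):
        spec = dataclasses.replace(
            base, n_benign=n_benign, n_malignant=n_malignant,
            seed=base.seed + 104729 * mi + seed,
        )
        cohort = generate_cohort(spec)
        for i, row in cohort.iterrows():
            sf = min(row.area_fraction / 100.0, tissue_fraction)
            core_id = f"{marker}_{row.core_id}"
            core = generate_core_image(
                CoreSpec(
                    image_width_px=image_size, image_height_px=image_size,
                    tissue_fraction=tissue_fraction, stained_fraction=sf,
                    blob_count=blob_count, noise_sd=noise_sd,
                    seed=(seed * 1_000_003 + 7919 * mi + i) % (2**31),
                ),
                core_id=core_id,
            )
            path = outdir / f"{core_id}.png"
            iio.imwrite(path, core.pixels)
            manifest_rows.append(
                dict(core_id=core_id, sample_id=row.core_id,
                     image_path=str(path), marker_name=marker,
                     diagnosis=row.diagnosis, gleason=row.gleason,
                     relapse=row.relapse)
            )
            truth_rows.append(
                dict(core_id=core_id,
                     true_stained_fraction=core.true_stained_fraction,
                     true_tissue_fraction=core.true_tissue_fraction)
            )
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)
    return manifest_path


def simulate_coloc_dataset(
    outdir: str | Path,
    n_pairs: int = 4,
    rho_nonrelapse: float = 0.73,
    rho_relapse: float = 0.60,
    n_slices: int = 4,
    n_pixels_per_slice: int = 64 * 64,
    seed: int = 0,
) -> Path:
    """Write a synthetic fluorescence dataset: one 16-bit multi-page TIFF per
    core (channel-major), matched relapse / non-relapse arms at the two target
    correlations, plus a pipeline manifest.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_pairs):
        for arm, rho in (("no", rho_nonrelapse), ("yes", rho_relapse)):
            spec = FluorSpec(
                n_slices=n_slices,
                channels=("FITC", "Cy3", "Cy5"),
                pairwise_rho=(("FITC", "Cy3", rho),),
                n_pixels_per_slice=n_pixels_per_slice,
                seed=(seed * 9973 + 31 * i + (1 if arm == "yes" else 0)) % (2**31),
            )
            stack = generate_fluorescence_stack(spec)
            arr = np.stack([stack.channels[c] for c in spec.channels])
            core_id = f"pair{i}_{arm}"
            path = outdir / f"{core_id}.tif"
            tifffile.imwrite(path, arr, photometric="minisblack")
            rows.append(
                dict(stack_path=str(path), core_id=core_id, pair_id=f"pair{i}",
                     relapse=arm, channels=";".join(spec.channels))
            )
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path
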