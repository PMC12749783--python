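"""Orchestration of the four study analyses over the site-level tables.

Stages (each callable on its own, all composed by :func:`run_all`):

1. in-person reliability — per-site inter-rater weighted kappa for MST and
   the two Pantone components, plus triplicate-colorimeter ITA ICC;
2. objective-vs-subjective dispersion — DBI/RSI of FST, MST and Pantone
   classes in the 2-D (L*, b*) colorimeter space;
3. photography-based reliability — TBP-vs-in-person MST kappa and paired
   shift tests per lighting mode, image-extracted-ITA-vs-colorimeter ICC
   per dermoscopy mode, and crowd-vs-in-person FST agreement with
   chi-squared accuracy breakdowns;
4. fairness — KS-based score-distribution audits for FST and MST.

Inputs are the pipeline's stable CSV schemas (see the synthetic study
generator, whose output is the reference implementation of those schemas).
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    agreement_heatmap,
    chi_squared_independence,
    concordance_by_class,
    icc_agreement,
    linear_weighted_kappa,
    paired_mean_difference,
)
from .colorspace import ita_values
from .crowd import crowd_vs_reference, majority_labels
from .dispersion import dispersion_compare, select_single_rating
from .errors import SchemaError, ZeroVariance
from .fairness import fairness_report
from .image_color import ImagePatch, image_ita, load_patch
from .scales import (
    DERMOSCOPY_MODES,
    K_FST,
    K_MST,
    K_PANTONE_PIGMENT,
    K_PANTONE_UNDERTONE,
    parse_pantone,
)

logger = logging.getLogger("tonescale")

__all__ = [
    "run_inperson_reliability",
    "run_dispersion",
    "run_photo_reliability",
    "run_fairness",
    "run_all",
    "load_patches",
    "manifest",
]

_SITE_COLUMNS = {
    "participant_id", "site_id", "site_kind", "anatomic_site", "fst",
    "mst_r1", "mst_r2", "pantone_r1", "pantone_r2",
}


def _check_sites(sites: pd.DataFrame) -> None:
    missing = _SITE_COLUMNS - set(sites.columns)
    if missing:
        raise SchemaError(f"sites table missing columns: {sorted(missing)}")
    if not sites["site_kind"].isin(["lesional", "nonlesional"]).all():
        raise SchemaError("site_kind must be 'lesional' or 'nonlesional'")
    fst = pd.to_numeric(sites["fst"], errors="coerce")
    if fst.isna().any() or (fst < 1).any() or (fst > K_FST).any():
        raise SchemaError("fst must be 1..6 on every site")


def _triplicate_ita(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site ITA of each colorimeter triplicate (rows with all 3 finite)."""
    cols = {}
    for rep in (1, 2, 3):
        L = pd.to_numeric(sites[f"colorimeter_L{rep}"], errors="coerce")
        b = pd.to_numeric(sites[f"colorimeter_b{rep}"], errors="coerce")
        cols[f"ita{rep}"] = ita_values(L.to_numpy(), b.to_numpy())
    out = pd.DataFrame(cols, index=sites.index)
    return out.dropna()


def run_inperson_reliability(sites: pd.DataFrame) -> dict:
    """Stage 1: inter-rater agreement tables and colorimeter ICC (4 tables)."""
    _check_sites(sites)
    out: dict = {}
    mst = sites.dropna(subset=["mst_r1", "mst_r2"])
    out["mst_kappa"] = agreement_heatmap(mst, "mst_r1", "mst_r2", K_MST)

    pant = sites.dropna(subset=["pantone_r1", "pantone_r2"]).copy()
    for rater in (1, 2):
        parsed = pant[f"pantone_r{rater}"].map(parse_pantone)
        pant[f"undertone_r{rater}"] = parsed.map(lambda t: t[0])
        pant[f"pigment_r{rater}"] = parsed.map(lambda t: t[1])
    out["pantone_pigment_kappa"] = agreement_heatmap(
        pant, "pigment_r1", "pigment_r2", K_PANTONE_PIGMENT
    )
    out["pantone_undertone_kappa"] = agreement_heatmap(
        pant, "undertone_r1", "undertone_r2", K_PANTONE_UNDERTONE
    )

    ita = _triplicate_ita(sites)
    rows = []

    def _icc_row(group: str, idx) -> dict:
        sub = ita.loc[ita.index.intersection(idx)]
        if len(sub) < 2:
            return {"group": group, "icc": float("nan"), "n": len(sub)}
        try:
            res = icc_agreement(sub.to_numpy())
            return {"group": group, "icc": res.icc, "n": res.n_subjects}
        except ZeroVariance:
            return {"group": group, "icc": float("nan"), "n": len(sub)}

    nonles = sites[sites["site_kind"] == "nonlesional"]
    for site, grp in sorted(nonles.groupby("anatomic_site"), key=lambda t: str(t[0])):
        rows.append(_icc_row(str(site), grp.index))
    rows.append(_icc_row("lesional", sites.index[sites["site_kind"] == "lesional"]))
    rows.append(_icc_row("all", sites.index))
    out["colorimeter_ita_icc"] = pd.DataFrame(rows)
    logger.info(
        "inperson_reliability: %d MST pairs, %d Pantone pairs, %d triplicate sites",
        len(mst), len(pant), len(ita),
    )
    return out


def dispersion_filter(sites: pd.DataFrame) -> pd.DataFrame:
    """Non-lesional, colorimeter-measured sites with >=1 MST and >=1 Pantone rating."""
    has_cm = sites[[f"colorimeter_{c}{r}" for c in "Lb" for r in (1, 2, 3)]].notna().all(axis=1)
    has_mst = sites[["mst_r1", "mst_r2"]].notna().any(axis=1)
    has_pant = sites[["pantone_r1", "pantone_r2"]].notna().any(axis=1)
    return sites[(sites["site_kind"] == "nonlesional") & has_cm & has_mst & has_pant]


def run_dispersion(sites: pd.DataFrame, seed: int) -> dict:
    """Stage 2: DBI/RSI of the three scales in the (L*, b*) colorimeter plane.

    One rating per site per scale is chosen at random (between the two
    raters) with the given seed; the seed is recorded in each report.
    """
    _check_sites(sites)
    sub = dispersion_filter(sites).copy()
    rng = np.random.default_rng(seed)
    mst_sel = select_single_rating(sub, "mst_r1", "mst_r2", rng).astype(int)
    pant_sel = select_single_rating(sub, "pantone_r1", "pantone_r2", rng)
    L = sub[["colorimeter_L1", "colorimeter_L2", "colorimeter_L3"]].mean(axis=1)
    b = sub[["colorimeter_b1", "colorimeter_b2", "colorimeter_b3"]].mean(axis=1)
    points = np.column_stack([L.to_numpy(), b.to_numpy()])
    labels = {
        "fst": sub["fst"].astype(int).to_numpy(),
        "mst": mst_sel.to_numpy(),
        "pantone": pant_sel.to_numpy(),
    }
    reports = dispersion_compare(
        points, labels, site_labels=sub["anatomic_site"].to_numpy(), seed=seed
    )
    reports["n_sites"] = len(sub)
    logger.info("dispersion: %d sites after filter, seed=%d", len(sub), seed)
    return reports


def load_patches(image_dir: str | Path, images: pd.DataFrame) -> dict:
    """Load PNG patches named <image_id>.png for every non-lesional image row."""
    image_dir = Path(image_dir)
    out = {}
    for image_id in images.loc[images["site_kind"] == "nonlesional", "image_id"]:
        path = image_dir / f"{image_id}.png"
        if path.exists():
            out[image_id] = load_patch(path).pixels
    return out


def run_photo_reliability(
    sites: pd.DataFrame,
    images: pd.DataFrame,
    patches: Mapping[str, np.ndarray],
    crowd: pd.DataFrame,
) -> dict:
    """Stage 3: photography-based agreement tables.

    Emits TBP XP/WL kappa heatmaps and paired shift tests, per-dermoscopy-
    mode image-ITA-vs-colorimeter ICC, and the crowd comparison (kappa,
    concordance, per-site kappa, chi-squared accuracy by mode and by site).
    """
    _check_sites(sites)
    out: dict = {}

    # TBP vs in-person (rater 1), per lighting mode.
    for mode in ("xp", "wl"):
        col = f"mst_tbp_{mode}"
        sub = sites.dropna(subset=["mst_r1", col])
        sub = sub[sub["site_kind"] == "nonlesional"]
        out[f"{mode}_kappa"] = agreement_heatmap(sub, "mst_r1", col, K_MST)
        out[f"{mode}_paired_test"] = paired_mean_difference(
            sub["mst_r1"].to_numpy(float), sub[col].to_numpy(float)
        )

    # Image-extracted ITA vs colorimeter ITA, per dermoscopy mode.
    trip = _triplicate_ita(sites)
    cm_ita = trip.mean(axis=1)
    site_of = dict(zip(images["image_id"], images["site_id"]))
    site_index = dict(zip(sites["site_id"], sites.index))
    icc_rows = []
    for mode in DERMOSCOPY_MODES:
        mode_imgs = images[(images["mode"] == mode) & (images["site_kind"] == "nonlesional")]
        pairs = []
        for image_id in mode_imgs["image_id"]:
            if image_id not in patches:
                continue
            idx = site_index[site_of[image_id]]
            if idx not in cm_ita.index:
                continue
            try:
                img_val = image_ita(ImagePatch(patches[image_id])).value
            except Exception:
                continue
            pairs.append((cm_ita.loc[idx], img_val))
        if len(pairs) >= 2:
            res = icc_agreement(np.asarray(pairs))
            icc_rows.append({"mode": mode, "icc": res.icc, "n": res.n_subjects})
        else:
            icc_rows.append({"mode": mode, "icc": float("nan"), "n": len(pairs)})
    out["image_ita_icc"] = pd.DataFrame(icc_rows)

    # Crowd vs in-person FST.
    fst_of_site = dict(zip(sites["site_id"], sites["fst"]))
    reference = pd.Series(
        {iid: fst_of_site[site_of[iid]] for iid in crowd["image_id"].unique()}
    )
    majority = majority_labels(crowd)
    table, kappa = crowd_vs_reference(majority, reference, k=K_FST)
    out["crowd_confusion"] = table
    out["crowd_kappa"] = kappa
    out["crowd_concordance"] = concordance_by_class(table)

    resolved = majority.dropna(subset=["label"]).copy()
    resolved["reference"] = resolved["image_id"].map(reference)
    resolved["correct"] = resolved["label"].astype(int) == resolved["reference"].astype(int)
    meta = images.set_index("image_id")
    resolved["mode"] = resolved["image_id"].map(meta["mode"])
    resolved["anatomic_site"] = resolved["image_id"].map(meta["site_id"]).map(
        dict(zip(sites["site_id"], sites["anatomic_site"]))
    )
    per_site_rows = []
    for site, grp in sorted(resolved.groupby("anatomic_site"), key=lambda t: str(t[0])):
        if len(grp) >= 2:
            res = linear_weighted_kappa(
                grp["reference"].astype(int), grp["label"].astype(int), K_FST
            )
            kap = float("nan") if res.degenerate else res.kappa
        else:
            kap = float("nan")
        per_site_rows.append({"group": site, "kappa": kap, "n": len(grp)})
    out["crowd_site_kappa"] = pd.DataFrame(per_site_rows)

    for factor in ("mode", "anatomic_site"):
        tab = pd.crosstab(resolved[factor], resolved["correct"])
        tab = tab.loc[(tab.sum(axis=1) > 0), :]
        out[f"crowd_accuracy_by_{factor}_chi2"] = chi_squared_independence(tab.to_numpy())
    logger.info(
        "photo_reliability: %d crowd images resolved of %d", len(resolved), len(majority)
    )
    return out


def run_fairness(scores: pd.DataFrame) -> dict:
    """Stage 4: KS fairness audits of the benign score distributions.

    Empty classes are omitted from the pairwise summaries (the report keeps
    their rows as NaN); a warning is logged for each.
    """
    required = {"lesion_id", "score", "fst", "mst"}
    missing = required - set(scores.columns)
    if missing:
        raise SchemaError(f"scores table missing columns: {sorted(missing)}")
    s = pd.to_numeric(scores["score"], errors="coerce")
    if s.isna().any() or (s < 0).any() or (s > 100).any():
        raise SchemaError("scores must be numeric in [0, 100]")
    out = {}
    for scale, k in (("fst", K_FST), ("mst", K_MST)):
        classes = scores[scale].astype(int)
        for lab in range(1, k + 1):
            if (classes == lab).sum() == 0:
                logger.warning("fairness: %s class %d empty; omitted from pairs", scale, lab)
        out[scale] = fairness_report(
            s.to_numpy(), classes.to_numpy(), scale, class_labels=range(1, k + 1)
        )
    return out


def run_all(
    sites: pd.DataFrame,
    images: pd.DataFrame,
    patches: Mapping[str, np.ndarray],
    crowd: pd.DataFrame,
    scores: pd.DataFrame,
    seed: int,
) -> dict:
    """Run the four stages and return their keyed outputs."""
    return {
        "inperson": run_inperson_reliability(sites),
        "dispersion": run_dispersion(sites, seed),
        "photo": run_photo_reliability(sites, images, patches, crowd),
        "fairness": run_fairness(scores),
    }


def manifest(config_dict: dict, seed: int, counts: dict) -> dict:
    """Run manifest: config hash, master seed, package version, stage counts."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "tonescale_version": __version__,
        "counts": counts,
    }
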