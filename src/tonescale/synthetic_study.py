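"""Seeded generator for a full synthetic skin-tone labeling study.

Produces every artifact the analysis pipeline consumes — a site-level table
with two raters' MST/Pantone ratings and colorimeter triplicates, rendered
dermoscopy-style image patches, a crowdsourced FST read log, and per-lesion
classifier scores — with the statistical structure the analyses assume:

* FST-balanced recruitment (10/12/11/10/11/10 participants for FST I..VI;
  64 total), each participant contributing 11 standardized non-lesional
  sites and 5-13 lesions;
* a class-conditional CIELAB color model: mean L* decreases monotonically
  across MST shades while b* rises then falls; FST is tied to MST through a
  noisy many-to-one map, so each FST class deliberately spans a *wider*
  range of true color than an MST shade — the structure the dispersion
  analysis is designed to detect;
* ordinal rater noise (a symmetric ±1/±2 error kernel, clipped at scale
  ends) giving inter-rater kappa a known generating value;
* colorimeter triplicate noise in L*/a*/b*, giving the triplicate-ITA ICC a
  known variance-ratio value;
* lighting-mode shifts: white-light TBP ratings biased lighter (negative
  MST shift) and cross-polarized slightly darker, plus per-dermoscopy-mode
  L*/b* offsets baked into rendered patches;
* a crowd of annotators with heterogeneous skill whose per-read correctness
  also depends on dermoscopy mode and anatomic site;
* benign-lesion malignancy scores from per-MST-class Beta distributions
  with the darkest-but-two shades (8-9) shifted upward.

All randomness flows from one master seed through named substreams; the
same seed reproduces every table byte-for-byte. Parameter defaults are the
study conditions, not claims about real skin; ``implied_kappa`` and
``implied_icc`` expose the generating values the estimators should recover.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .colorspace import LabColor, lab_to_rgb, ita_values
from .errors import ConfigError
from .image_color import ImagePatch
from .scales import (
    ANATOMIC_SITES,
    DERMOSCOPY_MODES,
    K_FST,
    K_MST,
    K_PANTONE_PIGMENT,
    K_PANTONE_UNDERTONE,
    pantone_code,
)

__all__ = [
    "StudyConfig",
    "SyntheticStudy",
    "generate",
    "true_site_color",
    "rate_with_noise",
    "render_patch",
    "simulate_scores",
    "implied_kappa",
    "implied_icc",
]

_STREAMS = (
    "participants",
    "colors",
    "ratings",
    "rater_select",
    "colorimeter",
    "tbp",
    "images",
    "crowd",
    "scores",
)


def _default_site_L_offsets() -> dict:
    # Sun-protected / callused sites lighter, exposed sites darker.
    return {
        "forehead": -2.0, "chest": 0.0, "abdomen": 1.0, "inner_upper_arm": 2.0,
        "inner_wrist": 1.5, "forearm": -2.0, "upper_back": -1.0, "lower_back": 0.0,
        "shin": -1.0, "calf": -1.0, "sole": 6.0,
    }


def _default_site_b_offsets() -> dict:
    return {
        "forehead": 0.5, "chest": 0.0, "abdomen": 0.0, "inner_upper_arm": -0.5,
        "inner_wrist": -0.5, "forearm": 0.5, "upper_back": 0.0, "lower_back": 0.0,
        "shin": 0.5, "calf": 0.5, "sole": -1.0,
    }


@dataclass
class StudyConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    # Recruitment (FST I..VI) and per-participant site structure.
    participants_per_fst: tuple = (10, 12, 11, 10, 11, 10)
    lesions_min: int = 5
    lesions_max: int = 13

    # Class-conditional color model (MST shades 1..10).
    mst_L_means: tuple = tuple(np.linspace(75.0, 30.0, K_MST))
    mst_a_means: tuple = tuple(np.linspace(7.0, 13.0, K_MST))
    mst_b_means: tuple = (14.0, 15.0, 16.0, 17.0, 18.0, 18.0, 17.0, 15.0, 13.0, 11.0)
    mst_within_sd: tuple = (2.5, 0.8, 1.2)  # site-to-site SD of (L*, a*, b*)
    site_L_offsets: dict = field(default_factory=_default_site_L_offsets)
    site_b_offsets: dict = field(default_factory=_default_site_b_offsets)

    # FST <-> latent MST tone map: center 1 + 1.8 (f - 1), wide Gaussian
    # spread so each photosensitivity class deliberately spans a broad range
    # of true color (the structure the dispersion analysis must detect).
    fst_latent_sd: float = 2.5

    # Ordinal rater noise kernels (offset -> probability; must sum to 1).
    mst_rater_kernel: dict = field(default_factory=lambda: {-1: 0.15, 0: 0.70, 1: 0.15})
    pantone_pigment_kernel: dict = field(
        default_factory=lambda: {-2: 0.075, -1: 0.175, 0: 0.50, 1: 0.175, 2: 0.075}
    )
    pantone_undertone_kernel: dict = field(
        default_factory=lambda: {-2: 0.075, -1: 0.175, 0: 0.50, 1: 0.175, 2: 0.075}
    )

    # Colorimeter triplicates.
    colorimeter_sd: tuple = (0.4, 0.25, 0.35)  # per-channel SD (L*, a*, b*)
    colorimeter_coverage: float = 0.734  # fraction of participants measured

    # TBP rating shifts (MST units on the latent tone before rounding).
    tbp_bias_xp: float = 0.15
    tbp_bias_wl: float = -0.70
    tbp_latent_sd: float = 0.8

    # Dermoscopy rendering: per-mode (dL*, db*) shifts and pixel noise, plus
    # a device color-processing model — auto exposure/white balance compress
    # the captured color toward a mid tone, which is what decouples
    # image-extracted ITA from colorimeter ITA.
    dermoscopy_mode_offsets: dict = field(
        default_factory=lambda: {
            "P-C": (-4.0, 3.0), "P-NC": (-2.5, 2.0), "NP-C": (4.0, -2.0), "NP-NC": (2.5, -1.0)
        }
    )
    dermoscopy_L_compression: float = 0.25  # slope of captured L* vs true L*
    dermoscopy_b_compression: float = 0.60
    dermoscopy_compression_center: tuple = (60.0, 16.0)  # (L*, b*) fixed point
    patch_size: int = 24
    patch_noise_sd: float = 3.0  # 8-bit RGB units

    # Crowd model. Annotators of the same image share a perceived tone (the
    # image-level bias), so annotator errors are correlated and majority
    # voting cannot vote the perception error away; per-mode and per-site
    # shifts make accuracy depend on dermoscopy lighting and anatomy.
    n_crowd_users: int = 60
    reads_per_image: int = 8
    gold_rate: float = 0.20
    crowd_skill_beta: tuple = (6.0, 3.0)  # Beta(a, b) per-user correctness
    crowd_error_kernel: dict = field(
        default_factory=lambda: {-2: 0.15, -1: 0.35, 1: 0.35, 2: 0.15}
    )
    crowd_image_bias_sd: float = 0.70  # SD of the shared perceived-FST shift
    crowd_mode_bias: dict = field(
        default_factory=lambda: {"P-C": 0.0, "P-NC": 0.1, "NP-C": -0.45, "NP-NC": -0.6}
    )
    crowd_site_bias: dict = field(
        default_factory=lambda: {"sole": -0.8, "forehead": 0.3}
    )

    # Benign malignancy-score model: per-MST-class Beta mean (fraction of 1)
    # and a common concentration; shades 8-9 shifted upward.
    score_mu: tuple = (0.020, 0.021, 0.023, 0.025, 0.027, 0.030, 0.035, 0.080, 0.100, 0.055)
    score_concentration: float = 8.0

    master_seed: int = 0

    def validate(self) -> None:
        if len(self.participants_per_fst) != K_FST or any(
            n < 1 for n in self.participants_per_fst
        ):
            raise ConfigError("need a positive participant count per FST class")
        if not (1 <= self.lesions_min <= self.lesions_max):
            raise ConfigError("lesion count range invalid")
        L = np.asarray(self.mst_L_means)
        if len(L) != K_MST or not (np.diff(L) < 0).all():
            raise ConfigError("MST L* means must be 10 strictly decreasing values")
        for name in ("mst_rater_kernel", "pantone_pigment_kernel",
                     "pantone_undertone_kernel"):
            kern = getattr(self, name)
            if abs(sum(kern.values()) - 1.0) > 1e-9 or any(p < 0 for p in kern.values()):
                raise ConfigError(f"{name} probabilities must be nonnegative and sum to 1")
        if abs(sum(self.crowd_error_kernel.values()) - 1.0) > 1e-9:
            raise ConfigError("crowd_error_kernel must sum to 1")
        for sd in (*self.mst_within_sd, *self.colorimeter_sd,
                   self.fst_latent_sd, self.tbp_latent_sd, self.patch_noise_sd):
            if sd < 0:
                raise ConfigError("SDs must be nonnegative")
        if not (0.0 <= self.colorimeter_coverage <= 1.0):
            raise ConfigError("colorimeter_coverage must be in [0, 1]")
        if not (0.0 <= self.gold_rate <= 1.0):
            raise ConfigError("gold_rate must be in [0, 1]")
        if len(self.score_mu) != K_MST or any(not 0 < m < 1 for m in self.score_mu):
            raise ConfigError("score_mu needs one mean in (0, 1) per MST shade")
        if self.n_crowd_users < 2:
            raise ConfigError("need at least 2 crowd users")


@dataclass
class SyntheticStudy:
    """All generated artifacts, in the schemas the pipeline consumes."""

    sites: pd.DataFrame
    images: pd.DataFrame
    patches: dict  # image_id -> (H, W, 3) uint8 array (non-lesional images)
    crowd: pd.DataFrame
    scores: pd.DataFrame
    truth: pd.DataFrame
    config: StudyConfig

    def write(self, out_dir: str | Path, write_images: bool = True) -> None:
        """Dump sites/images/crowd/scores/truth CSVs (and PNG patches)."""
        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(out / "sites.csv", index=False)
        self.images.to_csv(out / "images.csv", index=False)
        self.crowd.to_csv(out / "crowd.csv", index=False)
        self.scores.to_csv(out / "scores.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        if write_images:
            img_dir = out / "images"
            img_dir.mkdir(exist_ok=True)
            for image_id, arr in self.patches.items():
                Image.fromarray(arr).save(img_dir / f"{image_id}.png")


def _streams(master_seed: int) -> dict:
    children = np.random.SeedSequence(master_seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


def _fst_center(fst: int) -> float:
    return 1.0 + 1.8 * (fst - 1)


def true_site_color(
    config: StudyConfig, mst_class: int, anatomic_site: str, rng: np.random.Generator
) -> LabColor:
    """Class mean + anatomic-site offset + Gaussian within-class noise, clamped."""
    sdL, sda, sdb = config.mst_within_sd
    L = (
        config.mst_L_means[mst_class - 1]
        + config.site_L_offsets.get(anatomic_site, 0.0)
        + rng.normal(0.0, sdL)
    )
    a = config.mst_a_means[mst_class - 1] + rng.normal(0.0, sda)
    b = (
        config.mst_b_means[mst_class - 1]
        + config.site_b_offsets.get(anatomic_site, 0.0)
        + rng.normal(0.0, sdb)
    )
    return LabColor(
        float(np.clip(L, 1.0, 99.0)),
        float(np.clip(a, -100.0, 100.0)),
        float(np.clip(b, -100.0, 100.0)),
    )


def _kernel_arrays(kernel: dict) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.array(sorted(kernel))
    probs = np.array([kernel[o] for o in offsets], dtype=float)
    return offsets, probs


def rate_with_noise(
    true_class, kernel: dict, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Ordinal rating(s): truth plus a kernel-drawn offset, clipped to [1, k]."""
    true_class = np.atleast_1d(np.asarray(true_class, dtype=int))
    offsets, probs = _kernel_arrays(kernel)
    draw = rng.choice(offsets, size=true_class.shape, p=probs)
    return np.clip(true_class + draw, 1, k)


def render_patch(
    color: LabColor,
    mode_offset: tuple[float, float] = (0.0, 0.0),
    size: int = 24,
    noise_sd: float = 3.0,
    rng: np.random.Generator | None = None,
) -> ImagePatch:
    """Constant-color patch shifted by a lighting-mode (dL*, db*) offset.

    The shifted CIELAB color is converted to sRGB once; per-pixel Gaussian
    noise (8-bit units) is then added, so the per-channel median recovers
    the shifted color up to quantization.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    shifted = LabColor(
        float(np.clip(color.L + mode_offset[0], 0.0, 100.0)),
        color.a,
        float(np.clip(color.b + mode_offset[1], -127.0, 127.0)),
    )
    base = lab_to_rgb(shifted)
    px = np.array([base.r, base.g, base.b], dtype=float)[None, None, :]
    noisy = px + rng.normal(0.0, noise_sd, size=(size, size, 3))
    return ImagePatch(np.clip(np.rint(noisy), 0, 255).astype(np.uint8))


def simulate_scores(
    mst_class, config: StudyConfig, rng: np.random.Generator
) -> np.ndarray:
    """Benign malignancy scores (percent) from the per-class Beta model."""
    cls = np.atleast_1d(np.asarray(mst_class, dtype=int))
    mu = np.asarray(config.score_mu)[cls - 1]
    conc = config.score_concentration
    return rng.beta(mu * conc, (1.0 - mu) * conc) * 100.0


def _pigment_from_L(L: float) -> int:
    return int(np.clip(round(1 + 14 * (80.0 - L) / 55.0), 1, K_PANTONE_PIGMENT))


def _undertone_from_ab(a: float, b: float) -> int:
    return int(np.clip(round(5.5 + 0.5 * (b - a - 4.0)), 1, K_PANTONE_UNDERTONE))


def generate(config: StudyConfig | None = None) -> SyntheticStudy:
    """Generate the full synthetic study deterministically from the master seed."""
    config = StudyConfig() if config is None else config
    config.validate()
    rngs = _streams(config.master_seed)

    # Participants: FST-balanced recruitment; true MST tone from the noisy map.
    participants = []
    r_part = rngs["participants"]
    pid = 0
    for fst, n in enumerate(config.participants_per_fst, start=1):
        for _ in range(n):
            pid += 1
            latent = _fst_center(fst) + r_part.normal(0.0, config.fst_latent_sd)
            participants.append(
                {
                    "participant_id": f"P{pid:03d}",
                    "fst": fst,
                    "true_mst": int(np.clip(round(latent), 1, K_MST)),
                    "device": "ipod" if r_part.random() < 0.5 else "slr",
                }
            )
    part_df = pd.DataFrame(participants)
    n_cov = int(round(config.colorimeter_coverage * len(part_df)))
    covered = set(
        r_part.choice(part_df["participant_id"].to_numpy(), size=n_cov, replace=False)
    )

    # Sites: 11 standardized non-lesional + 5-13 lesional per participant.
    r_col = rngs["colors"]
    site_rows = []
    truth_rows = []
    for p in participants:
        n_lesions = int(r_part.integers(config.lesions_min, config.lesions_max + 1))
        site_specs = [("nonlesional", s) for s in ANATOMIC_SITES]
        site_specs += [
            ("lesional", ANATOMIC_SITES[int(r_part.integers(len(ANATOMIC_SITES)))])
            for _ in range(n_lesions)
        ]
        for i, (kind, anatomic) in enumerate(site_specs, start=1):
            site_id = f"{p['participant_id']}-S{i:02d}"
            color = true_site_color(config, p["true_mst"], anatomic, r_col)
            site_rows.append(
                {
                    "participant_id": p["participant_id"],
                    "site_id": site_id,
                    "site_kind": kind,
                    "anatomic_site": anatomic,
                    "fst": p["fst"],
                }
            )
            truth_rows.append(
                {
                    "site_id": site_id,
                    "participant_id": p["participant_id"],
                    "true_mst": p["true_mst"],
                    "true_L": color.L,
                    "true_a": color.a,
                    "true_b": color.b,
                }
            )
    sites = pd.DataFrame(site_rows)
    truth = pd.DataFrame(truth_rows)

    # In-person ratings: two independent raters per scale.
    r_rate = rngs["ratings"]
    true_mst_per_site = truth["true_mst"].to_numpy()
    for col in ("mst_r1", "mst_r2"):
        sites[col] = rate_with_noise(true_mst_per_site, config.mst_rater_kernel, K_MST, r_rate)
    true_pig = truth["true_L"].map(_pigment_from_L).to_numpy()
    true_und = np.array(
        [_undertone_from_ab(a, b) for a, b in zip(truth["true_a"], truth["true_b"])]
    )
    for col in ("pantone_r1", "pantone_r2"):
        pig = rate_with_noise(true_pig, config.pantone_pigment_kernel, K_PANTONE_PIGMENT, r_rate)
        und = rate_with_noise(true_und, config.pantone_undertone_kernel, K_PANTONE_UNDERTONE, r_rate)
        sites[col] = [pantone_code(u, g) for u, g in zip(und, pig)]

    # Colorimeter triplicates on covered participants' non-lesional sites.
    r_cm = rngs["colorimeter"]
    sdL, sda, sdb = config.colorimeter_sd
    for rep in (1, 2, 3):
        for ch in "Lab":
            sites[f"colorimeter_{ch}{rep}"] = np.nan
    cm_mask = sites["participant_id"].isin(covered) & (sites["site_kind"] == "nonlesional")
    idx = sites.index[cm_mask]
    tL = truth.loc[idx, "true_L"].to_numpy()
    ta = truth.loc[idx, "true_a"].to_numpy()
    tb = truth.loc[idx, "true_b"].to_numpy()
    for rep in (1, 2, 3):
        sites.loc[idx, f"colorimeter_L{rep}"] = tL + r_cm.normal(0, sdL, idx.size)
        sites.loc[idx, f"colorimeter_a{rep}"] = ta + r_cm.normal(0, sda, idx.size)
        sites.loc[idx, f"colorimeter_b{rep}"] = tb + r_cm.normal(0, sdb, idx.size)

    # TBP-based MST ratings (non-lesional sites) under XP and WL lighting.
    r_tbp = rngs["tbp"]
    nl = sites.index[sites["site_kind"] == "nonlesional"]
    t_nl = truth.loc[nl, "true_mst"].to_numpy()
    for mode, bias in (("xp", config.tbp_bias_xp), ("wl", config.tbp_bias_wl)):
        latent = t_nl + bias + r_tbp.normal(0.0, config.tbp_latent_sd, nl.size)
        col = np.full(len(sites), np.nan)
        col[nl] = np.clip(np.rint(latent), 1, K_MST)
        sites[f"mst_tbp_{mode}"] = col

    # Images: 4 dermoscopy modes per non-lesional site (rendered patches);
    # one mode-tagged image per lesional site for crowdsourcing/scoring.
    r_img = rngs["images"]
    device_of = dict(zip(part_df["participant_id"], part_df["device"]))
    color_of = {
        row.site_id: LabColor(row.true_L, row.true_a, row.true_b)
        for row in truth.itertuples()
    }
    image_rows = []
    patches: dict = {}
    L0, b0 = config.dermoscopy_compression_center
    cL, cb = config.dermoscopy_L_compression, config.dermoscopy_b_compression

    def _camera_color(c: LabColor) -> LabColor:
        # Device auto exposure/processing: captured color is pulled toward a
        # mid tone, so image color only weakly tracks true skin color.
        return LabColor(
            float(np.clip(L0 + cL * (c.L - L0), 0.0, 100.0)),
            c.a,
            float(np.clip(b0 + cb * (c.b - b0), -127.0, 127.0)),
        )

    for row in sites.itertuples():
        if row.site_kind == "nonlesional":
            for mode in DERMOSCOPY_MODES:
                image_id = f"{row.site_id}-{mode}"
                patch = render_patch(
                    _camera_color(color_of[row.site_id]),
                    config.dermoscopy_mode_offsets[mode],
                    config.patch_size,
                    config.patch_noise_sd,
                    r_img,
                )
                patches[image_id] = patch.pixels
                image_rows.append(
                    {
                        "image_id": image_id, "site_id": row.site_id,
                        "site_kind": "nonlesional", "mode": mode,
                        "device": device_of[row.participant_id],
                    }
                )
        else:
            mode = DERMOSCOPY_MODES[int(r_img.integers(len(DERMOSCOPY_MODES)))]
            image_rows.append(
                {
                    "image_id": f"{row.site_id}-{mode}", "site_id": row.site_id,
                    "site_kind": "lesional", "mode": mode,
                    "device": device_of[row.participant_id],
                }
            )
    images = pd.DataFrame(image_rows)

    # Crowd read log over lesional images.
    r_crowd = rngs["crowd"]
    skill = r_crowd.beta(*config.crowd_skill_beta, size=config.n_crowd_users)
    users = [f"U{u:03d}" for u in range(1, config.n_crowd_users + 1)]
    err_off, err_p = _kernel_arrays(config.crowd_error_kernel)
    fst_of_site = dict(zip(sites["site_id"], sites["fst"]))
    anatomic_of = dict(zip(sites["site_id"], sites["anatomic_site"]))
    lesional_images = images[images["site_kind"] == "lesional"].reset_index(drop=True)
    image_order = r_crowd.permutation(len(lesional_images))
    gold_flag = r_crowd.random(len(lesional_images)) < config.gold_rate
    order_counter = {u: 0 for u in users}
    crowd_rows = []
    for img_pos in image_order:
        img = lesional_images.iloc[img_pos]
        fst = fst_of_site[img["site_id"]]
        # Shared perceived tone of this image: true FST shifted by lighting
        # mode, anatomy, and an image-level random bias all readers see.
        latent = (
            fst
            + config.crowd_mode_bias.get(img["mode"], 0.0)
            + config.crowd_site_bias.get(anatomic_of[img["site_id"]], 0.0)
            + r_crowd.normal(0.0, config.crowd_image_bias_sd)
        )
        perceived = int(np.clip(round(latent), 1, K_FST))
        reader_ids = r_crowd.choice(
            config.n_crowd_users, size=min(config.reads_per_image, config.n_crowd_users),
            replace=False,
        )
        for uidx in reader_ids:
            p_correct = float(np.clip(skill[uidx], 0.05, 0.98))
            if r_crowd.random() < p_correct:
                label = perceived
            else:
                off = int(r_crowd.choice(err_off, p=err_p))
                label = int(np.clip(perceived + off, 1, K_FST))
            order_counter[users[uidx]] += 1
            crowd_rows.append(
                {
                    "user_id": users[uidx],
                    "image_id": img["image_id"],
                    "order": order_counter[users[uidx]],
                    "label": label,
                    "is_gold": bool(gold_flag[img_pos]),
                    "gold_label": fst if gold_flag[img_pos] else pd.NA,
                }
            )
    crowd = pd.DataFrame(crowd_rows)

    # Benign classifier scores per lesional site, keyed to the true MST shade.
    r_sc = rngs["scores"]
    lesional_sites = sites[sites["site_kind"] == "lesional"]
    t_mst = truth.set_index("site_id").loc[lesional_sites["site_id"], "true_mst"].to_numpy()
    scores = pd.DataFrame(
        {
            "lesion_id": lesional_sites["site_id"].to_numpy(),
            "score": simulate_scores(t_mst, config, r_sc),
            "fst": lesional_sites["fst"].to_numpy(),
            "mst": lesional_sites["mst_r1"].to_numpy(),
        }
    )

    return SyntheticStudy(
        sites=sites, images=images, patches=patches, crowd=crowd,
        scores=scores, truth=truth, config=config,
    )


def implied_kappa(true_classes, kernel: dict, k: int) -> float:
    """Linear-weighted kappa implied by the rater noise kernel.

    Two raters independently perturb each true class with the clipped
    kernel; the joint rating distribution is known in closed form, and the
    kappa of that distribution is the value the sample estimate converges
    to. Used as the generating-value oracle in parameter-recovery checks.
    """
    true_classes = np.asarray(true_classes, dtype=int)
    p_true = np.bincount(true_classes, minlength=k + 1)[1:] / true_classes.size
    offsets, probs = _kernel_arrays(kernel)
    K = np.zeros((k, k))  # K[t, r] = P(rating r+1 | truth t+1), clipped
    for t in range(k):
        for off, p in zip(offsets, probs):
            r = int(np.clip(t + off, 0, k - 1))
            K[t, r] += p
    joint = np.einsum("t,ti,tj->ij", p_true, K, K)
    idx = np.arange(k)
    w = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    expected = np.outer(joint.sum(axis=1), joint.sum(axis=0))
    return 1.0 - float((w * joint).sum()) / float((w * expected).sum())


def implied_icc(true_L, true_b, sd_L: float, sd_b: float) -> float:
    """Variance-ratio ICC implied by the colorimeter triplicate noise.

    Between-site variance of the true ITA against the delta-method noise
    variance of ITA propagated from the per-channel L*/b* measurement SDs:
    ICC = var_between / (var_between + mean noise variance).
    """
    L = np.asarray(true_L, dtype=float)
    b = np.asarray(true_b, dtype=float)
    ita = ita_values(L, b)
    deg = 180.0 / np.pi
    u = (L - 50.0) / b
    dL = deg / (b * (1.0 + u**2))
    db = -deg * (L - 50.0) / (b**2 * (1.0 + u**2))
    noise_var = (dL**2) * sd_L**2 + (db**2) * sd_b**2
    var_between = float(np.var(ita))
    return var_between / (var_between + float(noise_var.mean()))
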