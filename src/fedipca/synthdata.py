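"""Synthetic multi-site 3D imaging cohorts with non-IID structure.

Generates desk-scale analogs of a multi-center prostate-MRI classification
study: each site has its own gray-value distribution (a scanner-shift
analog), its own positive-class prevalence, and an ellipsoidal organ mask.
Positive cases carry a single ellipsoidal lesion blob of shifted intensity
placed uniformly at random inside the mask.

Volumes are written as NIfTI, labels and splits as a CSV manifest, so the
rest of the pipeline can also be pointed at real data laid out the same way.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "SiteProfile",
    "SyntheticCohort",
    "generate_site",
    "generate_multisite",
    "split_train_val",
    "default_profiles",
    "write_cohort",
    "read_cohort",
    "load_profiles",
]


@dataclass(frozen=True)
class SiteProfile:
    """Generative parameters of one synthetic imaging center.

    ``intensity_mean``/``intensity_sd`` set the per-case baseline gray value
    (case-level variation, shared by every voxel of a case, the way a
    scanner's gain drifts per acquisition); ``noise_sd`` adds independent
    per-voxel noise on top. ``lesion_effect`` is the additive contrast of
    the lesion blob in positive cases.
    """

    site_id: str
    n_cases: int = 350
    prevalence: float = 0.3
    resolution: int = 12
    intensity_mean: float = 100.0
    intensity_sd: float = 8.0
    lesion_effect: float = 50.0
    noise_sd: float = 10.0
    mask_radius_frac: float = 0.8
    lesion_radius_frac: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be a nonempty string")
        if self.n_cases < 2:
            raise ValueError(f"n_cases must be >= 2, got {self.n_cases}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.resolution < 4:
            raise ValueError(f"resolution must be >= 4, got {self.resolution}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 < self.mask_radius_frac <= 1.0:
            raise ValueError(
                f"mask_radius_frac must be in (0, 1], got {self.mask_radius_frac}"
            )


@dataclass
class SyntheticCohort:
    """One site's generated cases: volumes, masks, binary labels, split tags."""

    site_id: str
    volumes: np.ndarray  # (n, r, r, r) float64
    masks: np.ndarray  # (n, r, r, r) uint8
    labels: np.ndarray  # (n,) int, 1 = positive
    split: np.ndarray = field(default=None)  # (n,) object, in {train,validation,test}
    case_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.volumes)
        if self.split is None:
            self.split = np.array(["train"] * n, dtype=object)
        if self.case_ids is None:
            self.case_ids = np.array(
                [f"{self.site_id}_{i:04d}" for i in range(n)], dtype=object
            )
        if not (len(self.masks) == len(self.labels) == len(self.split) == n):
            raise ValueError("volumes, masks, labels and split must share length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def n_cases(self) -> int:
        return len(self.volumes)

    def subset(self, idx: np.ndarray) -> "SyntheticCohort":
        return SyntheticCohort(
            site_id=self.site_id,
            volumes=self.volumes[idx],
            masks=self.masks[idx],
            labels=self.labels[idx],
            split=self.split[idx],
            case_ids=self.case_ids[idx],
        )


def _ellipsoid_mask(resolution: int, center: np.ndarray, radius: float) -> np.ndarray:
    grid = np.indices((resolution,) * 3).astype(float)
    dist2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
    return (dist2 <= radius**2).astype(np.uint8)


def generate_site(profile: SiteProfile) -> SyntheticCohort:
    """Generate one site's cohort, deterministically for a fixed seed.

    Exactly ``round(n_cases * prevalence)`` cases are positive (the count is
    deterministic; which cases are positive is randomized). Positive cases
    receive one lesion blob of elevated intensity whose center is drawn
    uniformly among in-mask voxels. All voxels outside the organ mask are
    exactly zero.
    """
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    r = profile.resolution
    n = profile.n_cases

    half = (r - 1) / 2.0
    center = np.full(3, half)
    organ = _ellipsoid_mask(r, center, profile.mask_radius_frac * half)
    in_mask = np.argwhere(organ.ravel()).ravel()

    n_pos = int(round(n * profile.prevalence))
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1

    lesion_radius = max(1.0, profile.lesion_radius_frac * profile.mask_radius_frac * half)
    volumes = np.empty((n, r, r, r))
    masks = np.broadcast_to(organ, (n, r, r, r)).copy()
    for i in range(n):
        base = rng.normal(profile.intensity_mean, profile.intensity_sd)
        vol = base + rng.normal(0.0, profile.noise_sd, size=(r, r, r))
        if labels[i] == 1:
            flat_idx = rng.choice(in_mask)
            blob_center = np.array(np.unravel_index(flat_idx, (r, r, r)), dtype=float)
            blob = _ellipsoid_mask(r, blob_center, lesion_radius)
            vol = vol + profile.lesion_effect * blob
        volumes[i] = vol * organ

    return SyntheticCohort(
        site_id=profile.site_id, volumes=volumes, masks=masks, labels=labels
    )


def generate_multisite(profiles: Sequence[SiteProfile]) -> list[SyntheticCohort]:
    """Generate one cohort per profile; site_ids must be unique."""
    ids = [p.site_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate site_id among {ids}")
    return [generate_site(p) for p in profiles]


def split_train_val(
    cohort: SyntheticCohort, train_fraction: float, seed: int
) -> SyntheticCohort:
    """Tag each case train/validation, stratified by label.

    The train count is ``round(n * train_fraction)``; within each class the
    per-class train count is rounded the same way and the remainder balanced
    so the totals come out exact.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = cohort.n_cases
    n_train = int(round(n * train_fraction))
    rng = np.random.default_rng(seed)
    counts = np.bincount(cohort.labels, minlength=2)
    if counts.min() < 2:
        raise ValueError(
            "each class needs >= 2 members to stratify; got counts "
            f"{counts.tolist()}"
        )

    split = np.array(["validation"] * n, dtype=object)
    # per-class train counts: proportional rounding, then fix the total
    per_class = [int(round(counts[c] * train_fraction)) for c in (0, 1)]
    excess = sum(per_class) - n_train
    # adjust the larger class to hit the exact overall train count
    big = int(np.argmax(counts))
    per_class[big] -= excess
    for c in (0, 1):
        members = np.flatnonzero(cohort.labels == c)
        chosen = rng.choice(members, size=per_class[c], replace=False)
        split[chosen] = "train"
    out = SyntheticCohort(
        site_id=cohort.site_id,
        volumes=cohort.volumes,
        masks=cohort.masks,
        labels=cohort.labels,
        split=split,
        case_ids=cohort.case_ids,
    )
    return out


def default_profiles(seed: int = 12345) -> list[SiteProfile]:
    """The default three-site study configuration.

    Two training/validation sites and one held-out test site, with sizes
    800/350/350, prevalences 0.295/0.311/0.228 and staggered gray-value
    baselines emulating different scanner vendors.
    """
    return [
        SiteProfile(
            site_id="site_a", n_cases=800, prevalence=0.295,
            intensity_mean=100.0, seed=seed,
        ),
        SiteProfile(
            site_id="site_b", n_cases=350, prevalence=0.311,
            intensity_mean=130.0, seed=seed + 1,
        ),
        SiteProfile(
            site_id="site_c", n_cases=350, prevalence=0.228,
            intensity_mean=160.0, seed=seed + 2,
        ),
    ]


# ---------------------------------------------------------------------------
# On-disk layout: NIfTI volumes + masks, CSV manifest, YAML profiles
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write one cohort as NIfTI files plus a CSV manifest; returns the dir."""
    import nibabel as nib

    out = Path(out_dir) / cohort.site_id
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for i, cid in enumerate(cohort.case_ids):
        nib.save(nib.Nifti1Image(cohort.volumes[i], affine), out / f"{cid}.nii.gz")
        nib.save(
            nib.Nifti1Image(cohort.masks[i].astype(np.uint8), affine),
            out / f"{cid}_mask.nii.gz",
        )
    with open(out / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "site_id", "label", "split"])
        for cid, lab, sp in zip(cohort.case_ids, cohort.labels, cohort.split):
            w.writerow([cid, cohort.site_id, int(lab), sp])
    return out


def read_cohort(site_dir: str | Path) -> SyntheticCohort:
    """Read a cohort from the ``write_cohort`` layout."""
    import nibabel as nib

    site_dir = Path(site_dir)
    rows = list(csv.DictReader(open(site_dir / "manifest.csv")))
    if not rows:
        raise ValueError(f"empty manifest in {site_dir}")
    volumes, masks, labels, split, case_ids = [], [], [], [], []
    for row in rows:
        cid = row["case_id"]
        volumes.append(np.asarray(nib.load(site_dir / f"{cid}.nii.gz").dataobj))
        masks.append(np.asarray(nib.load(site_dir / f"{cid}_mask.nii.gz").dataobj))
        labels.append(int(row["label"]))
        split.append(row["split"])
        case_ids.append(cid)
    return SyntheticCohort(
        site_id=rows[0]["site_id"],
        volumes=np.stack(volumes),
        masks=np.stack(masks).astype(np.uint8),
        labels=np.array(labels),
        split=np.array(split, dtype=object),
        case_ids=np.array(case_ids, dtype=object),
    )


_PROFILE_FIELDS = set(SiteProfile.__dataclass_fields__)


def load_profiles(path: str | Path) -> list[SiteProfile]:
    """Load site profiles from a YAML/JSON file with a top-level ``sites:`` key."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "sites" not in doc:
        raise ValueError("profile file must contain a top-level 'sites:' list")
    profiles = []
    for entry in doc["sites"]:
        unknown = set(entry) - _PROFILE_FIELDS
        if unknown:
            raise ValueError(f"unknown profile fields: {sorted(unknown)}")
        profiles.append(SiteProfile(**entry))
    return profiles
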