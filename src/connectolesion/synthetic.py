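"""Synthetic cohorts of structural connectomes with planted lesion effects.

The generator emulates the statistical structure that tractography-derived
connectomes of a chronic-stroke cohort exhibit, so the whole analysis
pipeline can be exercised end to end without imaging data:

* a bilateral 82-node parcellation (41 regions per hemisphere);
* per-subject symmetric streamline-count matrices with a
  distance-dependent expected profile on a per-hemisphere ring embedding
  (strong short-range connections, sparse long-range ones, strongest
  interhemispheric connections between homotopic regions) and negative-
  binomial count noise;
* a patient group whose lesioned hemisphere carries multiplicatively
  attenuated connectivity, concentrated on a cortico-subcortical motor
  subnetwork and on long-range edges, with a milder contralesional
  attenuation;
* clinical motor scores (grip-strength difference between hands, and the
  upper-extremity Fugl-Meyer score near its ceiling of 66), optionally
  correlated with the planted lesion severity.

All randomness derives from one cohort seed through documented per-subject
substreams, so a fixed seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import read_matrix_csv, write_matrix_csv, write_nodes_tsv, read_nodes_tsv
from .parcellation import Parcellation, make_parcellation

#: Cortico-subcortical motor subnetwork carrying the planted deficit.
DEFAULT_TARGET_REGIONS: frozenset[str] = frozenset(
    {
        "precentral",
        "postcentral",
        "superiorparietal",
        "superiortemporal",
        "insula",
        "caudate",
        "putamen",
        "pallidum",
        "thalamus",
    }
)

# Expected-count profile of the healthy generative model.  Counts decay
# with ring distance within a hemisphere (lattice part) and a fixed set of
# strong long-range shortcut pairs makes the profile small-world;
# interhemispheric connections are dominated by homotopic pairs.  Values
# were fixed once so that weighted network density lands in the 0.4-0.8
# range and group-average networks are small-world-like: clustering well
# above matched random nulls, efficiency comparable to them.
HEALTHY_PROFILE = {
    "intra_scale": 400.0,  # expected count of a nearest-neighbour edge
    "intra_decay": 1.5,  # e-folding ring distance of intra-hemisphere counts
    "n_shortcuts": 45,  # strong long-range shortcut pairs per hemisphere
    "shortcut_scale": 300.0,  # expected count of a shortcut edge
    "shortcut_min_distance": 6,  # shortcuts span more than the lattice range
    "shortcut_seed": 12345,  # fixed pattern: part of the atlas embedding
    "inter_homotopic": 220.0,  # expected homotopic interhemispheric count
    "inter_scale": 25.0,  # expected count scale of heterotopic pairs
    "inter_decay": 2.0,
    "dispersion": 0.5,  # negative-binomial alpha: var = mu + alpha * mu^2
}


@dataclass(frozen=True)
class LesionSpec:
    """Multiplicative attenuation pattern of a focal subcortical lesion.

    Edges incident to ``target_regions`` in the lesioned hemisphere are
    scaled by ``ipsilesional_attenuation``; remaining ipsilesional edges by
    the milder sqrt of that factor; contralesional edges by
    ``contralesional_attenuation`` (a diaschisis-like remote effect); and
    the longest tercile of ipsilesional edges additionally by
    ``long_range_extra_attenuation``.
    """

    side: str = "left"
    target_regions: frozenset[str] = DEFAULT_TARGET_REGIONS
    ipsilesional_attenuation: float = 0.50
    contralesional_attenuation: float = 0.90
    long_range_extra_attenuation: float = 0.25

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"lesion side must be 'left' or 'right', got {self.side!r}")
        for name in (
            "ipsilesional_attenuation",
            "contralesional_attenuation",
            "long_range_extra_attenuation",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.contralesional_attenuation < self.ipsilesional_attenuation:
            raise ValueError(
                "contralesional attenuation must be milder (>=) than ipsilesional"
            )


@dataclass
class Subject:
    id: str
    group: str  # patient | control
    lesion: LesionSpec | None
    grip_delta: float  # affected-vs-unaffected grip-strength difference, kg
    uefm: int  # upper-extremity Fugl-Meyer score, 0..66
    counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.group == "patient" and self.lesion is None:
            raise ValueError("patients must carry a LesionSpec")
        if self.group == "control" and self.lesion is not None:
            raise ValueError("controls must not carry a LesionSpec")
        if not 0 <= self.uefm <= 66:
            raise ValueError("UEFM must lie in 0..66")


@dataclass
class Cohort:
    parcellation: Parcellation
    subjects: list[Subject]
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def patients(self) -> list[Subject]:
        return [s for s in self.subjects if s.group == "patient"]

    @property
    def controls(self) -> list[Subject]:
        return [s for s in self.subjects if s.group == "control"]


# ---------------------------------------------------------------------------
# Healthy count model
# ---------------------------------------------------------------------------

def _ring_distance(pos: np.ndarray, n_ring: int) -> np.ndarray:
    d = np.abs(pos[:, None] - pos[None, :])
    return np.minimum(d, n_ring - d)


def shortcut_pairs(
    n_hemi: int,
    n_shortcuts: int,
    min_distance: int,
    seed: int,
) -> list[tuple[int, int]]:
    """The fixed long-range shortcut pair set of the small-world profile.

    Deterministic given its parameters; the same within-hemisphere pairs
    are used in both hemispheres (mirroring the bilateral atlas symmetry).
    """
    rs = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    seen = set()
    while len(pairs) < n_shortcuts:
        i, j = (int(v) for v in rs.integers(0, n_hemi, 2))
        d = min(abs(i - j), n_hemi - abs(i - j))
        key = (min(i, j), max(i, j))
        if d >= min_distance and key not in seen:
            seen.add(key)
            pairs.append(key)
    return pairs


def expected_counts(parc: Parcellation, profile: dict | None = None) -> np.ndarray:
    """Deterministic expected streamline-count matrix of the healthy model."""
    p = dict(HEALTHY_PROFILE)
    if profile:
        p.update(profile)
    n = parc.n_nodes
    n_hemi = parc.n_per_hemisphere
    pos = parc.ring_position()
    d = _ring_distance(pos, n_hemi)
    hemi = parc.nodes["hemisphere"].to_numpy()
    same_hemi = hemi[:, None] == hemi[None, :]
    names = parc.nodes["name"].to_numpy()
    homotopic = names[:, None] == names[None, :]

    mu = np.zeros((n, n))
    intra = p["intra_scale"] * np.exp(-(d - 1) / p["intra_decay"])
    mu[same_hemi] = intra[same_hemi]
    inter = p["inter_scale"] * np.exp(-d / p["inter_decay"])
    mu[~same_hemi] = inter[~same_hemi]
    mu[homotopic & ~same_hemi] = p["inter_homotopic"]
    if p["n_shortcuts"] > 0:
        pairs = shortcut_pairs(
            n_hemi, p["n_shortcuts"], p["shortcut_min_distance"], p["shortcut_seed"]
        )
        offsets = [
            parc.hemisphere_index("left"),
            parc.hemisphere_index("right"),
        ]
        for idx in offsets:
            for i, j in pairs:
                a, b = idx[i], idx[j]
                mu[a, b] = mu[b, a] = p["shortcut_scale"]
    np.fill_diagonal(mu, 0.0)
    return mu


def sample_healthy_counts(
    parc: Parcellation,
    seed: int | np.random.Generator,
    profile: dict | None = None,
) -> np.ndarray:
    """One symmetric negative-binomial streamline-count matrix."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = dict(HEALTHY_PROFILE)
    if profile:
        p.update(profile)
    mu = expected_counts(parc, p)
    n = parc.n_nodes
    iu = np.triu_indices(n, k=1)
    alpha = p["dispersion"]
    m = mu[iu]
    # gamma-Poisson mixture: var = mu + alpha * mu^2
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * m)
    vals = rng.poisson(lam)
    counts = np.zeros((n, n))
    counts[iu] = vals
    counts += counts.T
    return counts


# ---------------------------------------------------------------------------
# Lesion planting
# ---------------------------------------------------------------------------

def apply_synthetic_lesion(
    counts: np.ndarray,
    parc: Parcellation,
    spec: LesionSpec,
    seed: int | np.random.Generator,
    noise_sd: float = 0.05,
) -> np.ndarray:
    """Attenuate a healthy count matrix according to a lesion pattern.

    The output is re-symmetrised and carries multiplicative log-normal
    noise of scale ``noise_sd`` (0 disables noise, making the attenuation
    exact).
    """
    counts = np.asarray(counts, dtype=float)
    if not np.array_equal(counts, counts.T):
        raise ValueError("counts must be symmetric")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = parc.n_nodes
    n_hemi = parc.n_per_hemisphere
    ipsi = spec.side
    contra = "right" if ipsi == "left" else "left"

    hemi = parc.nodes["hemisphere"].to_numpy()
    names = parc.nodes["name"].to_numpy()
    is_ipsi = hemi == ipsi
    is_contra = hemi == contra
    is_target = is_ipsi & np.isin(names, list(spec.target_regions))

    f_ipsi = spec.ipsilesional_attenuation
    f_mild = np.sqrt(f_ipsi)  # milder attenuation of off-target ipsilesional edges
    f_contra = spec.contralesional_attenuation

    factor = np.ones((n, n))
    both_ipsi = is_ipsi[:, None] & is_ipsi[None, :]
    both_contra = is_contra[:, None] & is_contra[None, :]
    interhemi = ~(both_ipsi | both_contra)
    factor[both_ipsi] = f_mild
    factor[both_contra] = f_contra
    factor[interhemi] = np.sqrt(f_mild * f_contra)
    touches_target = is_target[:, None] | is_target[None, :]
    factor[touches_target] = f_ipsi

    # extra attenuation of the longest tercile of ipsilesional edges
    pos = parc.ring_position()
    d = _ring_distance(pos, n_hemi)
    intra_ipsi = both_ipsi.copy()
    np.fill_diagonal(intra_ipsi, False)
    dists = d[intra_ipsi]
    if len(dists):
        cutoff = np.quantile(np.unique(dists), 2 / 3)
        long_range = intra_ipsi & (d > cutoff)
        factor[long_range] *= spec.long_range_extra_attenuation

    out = counts * factor
    if noise_sd > 0:
        iu = np.triu_indices(n, k=1)
        noise = np.zeros((n, n))
        noise[iu] = rng.normal(0.0, noise_sd, size=len(iu[0]))
        noise += noise.T
        out = out * np.exp(noise)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def _subject_rng(cohort_seed: int, index: int) -> np.random.Generator:
    # per-subject substream: cohort seed plus the subject index
    return np.random.default_rng([cohort_seed, index])


def sample_cohort(
    n_patients: int = 17,
    n_controls: int = 21,
    n_left_lesions: int = 8,
    seed: int = 0,
    lesion: LesionSpec | None = None,
    severity_score_corr: float = 0.0,
    noise_sd: float = 0.05,
    parcellation: Parcellation | None = None,
) -> Cohort:
    """Sample a full cohort of patients and controls with connectomes.

    Patients receive the planted lesion (``n_left_lesions`` on the left,
    the remainder on the right, assigned in a seeded random order) plus
    clinical scores: the grip-strength difference has a standardised
    effect versus zero near Cohen's d = 1 and UEFM concentrates near its
    ceiling.  ``severity_score_corr`` couples per-patient lesion severity
    to the motor scores (0 = no association).
    """
    if n_left_lesions > n_patients:
        raise ValueError("n_left_lesions cannot exceed n_patients")
    if not -1 <= severity_score_corr <= 1:
        raise ValueError("severity_score_corr must lie in [-1, 1]")
    base_lesion = lesion if lesion is not None else LesionSpec()
    parc = parcellation if parcellation is not None else make_parcellation(seed)

    sides = ["left"] * n_left_lesions + ["right"] * (n_patients - n_left_lesions)
    rng_cohort = _subject_rng(seed, 10**6)
    rng_cohort.shuffle(sides)

    subjects: list[Subject] = []
    for i in range(n_patients):
        rng = _subject_rng(seed, i)
        healthy = sample_healthy_counts(parc, rng)
        # latent severity modulates attenuation depth and, optionally, scores
        z_sev = rng.normal()
        z_ind = rng.normal()
        rho = severity_score_corr
        z_score = rho * z_sev + np.sqrt(max(0.0, 1 - rho**2)) * z_ind
        sev_scale = float(np.exp(0.15 * z_sev))  # >1 = deeper attenuation
        spec_i = replace(
            base_lesion,
            side=sides[i],
            ipsilesional_attenuation=float(
                np.clip(base_lesion.ipsilesional_attenuation**sev_scale, 0.02, 1.0)
            ),
        )
        if spec_i.contralesional_attenuation < spec_i.ipsilesional_attenuation:
            spec_i = replace(
                spec_i, contralesional_attenuation=spec_i.ipsilesional_attenuation
            )
        counts = apply_synthetic_lesion(healthy, parc, spec_i, rng, noise_sd=noise_sd)
        # grip-strength difference: Cohen's d ~ 1 versus zero; higher
        # severity lowers the score when a coupling is requested
        grip = 7.0 + 6.6 * (-z_score if rho != 0 else z_ind)
        # UEFM near ceiling (median 66, IQR reaching into the low 60s)
        if rho != 0:
            deficit = max(0.0, 3.0 * z_score + rng.normal(0, 1))
        else:
            deficit = max(0.0, rng.normal(0, 1)) * rng.poisson(3)
        uefm = int(np.clip(round(66 - deficit), 0, 66))
        subjects.append(
            Subject(
                id=f"patient_{i:02d}",
                group="patient",
                lesion=spec_i,
                grip_delta=float(grip),
                uefm=uefm,
                counts=counts,
            )
        )
    for i in range(n_controls):
        rng = _subject_rng(seed, n_patients + i)
        counts = sample_healthy_counts(parc, rng)
        grip = float(rng.normal(0.0, 1.5))  # no systematic hand difference
        uefm = 66
        subjects.append(
            Subject(
                id=f"control_{i:02d}",
                group="control",
                lesion=None,
                grip_delta=grip,
                uefm=uefm,
                counts=counts,
            )
        )
    params = {
        "n_patients": n_patients,
        "n_controls": n_controls,
        "n_left_lesions": n_left_lesions,
        "severity_score_corr": severity_score_corr,
        "noise_sd": noise_sd,
        "lesion": {
            "target_regions": sorted(base_lesion.target_regions),
            "ipsilesional_attenuation": base_lesion.ipsilesional_attenuation,
            "contralesional_attenuation": base_lesion.contralesional_attenuation,
            "long_range_extra_attenuation": base_lesion.long_range_extra_attenuation,
        },
        "profile": dict(HEALTHY_PROFILE),
    }
    return Cohort(parcellation=parc, subjects=subjects, seed=seed, params=params)


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, directory: str | Path) -> list[Path]:
    """Write per-subject count CSVs, nodes.tsv, subjects.tsv, manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for s in cohort.subjects:
        if s.counts is None:
            raise ValueError(f"subject {s.id} has no count matrix")
        p = directory / f"{s.id}.csv"
        write_matrix_csv(p, s.counts)
        written.append(p)
    nodes_path = directory / "nodes.tsv"
    write_nodes_tsv(nodes_path, cohort.parcellation.nodes)
    written.append(nodes_path)
    subj_path = directory / "subjects.tsv"
    pd.DataFrame(
        [
            {
                "id": s.id,
                "group": s.group,
                "lesion_side": s.lesion.side if s.lesion else "",
                "grip_delta_kg": repr(float(s.grip_delta)),
                "uefm": s.uefm,
            }
            for s in cohort.subjects
        ]
    ).to_csv(subj_path, sep="\t", index=False)
    written.append(subj_path)
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump({"seed": cohort.seed, "params": cohort.params}, fh, indent=2)
    written.append(manifest_path)
    return written


def read_cohort(directory: str | Path) -> Cohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    parc = Parcellation(nodes=read_nodes_tsv(directory / "nodes.tsv"))
    subj_table = pd.read_csv(
        directory / "subjects.tsv", sep="\t", float_precision="round_trip"
    )
    lesion_params = manifest["params"].get("lesion", {})
    subjects = []
    for _, row in subj_table.iterrows():
        lesion = None
        if row["group"] == "patient":
            lesion = LesionSpec(
                side=row["lesion_side"],
                target_regions=frozenset(lesion_params.get(
                    "target_regions", DEFAULT_TARGET_REGIONS)),
                ipsilesional_attenuation=lesion_params.get(
                    "ipsilesional_attenuation", 0.5),
                contralesional_attenuation=lesion_params.get(
                    "contralesional_attenuation", 0.9),
                long_range_extra_attenuation=lesion_params.get(
                    "long_range_extra_attenuation", 0.25),
            )
        subjects.append(
            Subject(
                id=row["id"],
                group=row["group"],
                lesion=lesion,
                grip_delta=float(row["grip_delta_kg"]),
                uefm=int(row["uefm"]),
                counts=read_matrix_csv(directory / f"{row['id']}.csv"),
            )
        )
    return Cohort(
        parcellation=parc,
        subjects=subjects,
        seed=manifest["seed"],
        params=manifest["params"],
    )
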