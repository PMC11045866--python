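"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one data stream of a fiber-intervention /
microbiota-transplant study:

* ``gen_cohort`` - paired pre/post metabolic panels for an intervention
  cohort with a planted responder subset;
* ``gen_paired_communities`` - paired pre/post gut community compositions
  on a shared random phylogeny, with individual-specific shift magnitudes
  (responders shift more);
* ``gen_bead_cloud`` - 3D microsphere coordinates over an epithelial
  surface, with an exponential penetration-depth law plus a dense mode at
  the mucus surface;
* ``gen_mucus_experiment`` - timed mucus-thickness measurements with
  group-structured growth rates;
* ``gen_assay_plate`` - standard-curve plates with planted enzyme
  activities;
* ``gen_metabolite_table`` - metabolite peak areas with planted fold
  changes and missing values.

One global seed governs a per-generator derived seed stream (a fixed
registry of stream ids), so adding a generator never perturbs the output
of another.  Identical configuration implies bit-identical output.

``noise_sd`` is a single relative noise dial: each generator scales it by
the natural magnitude of its measurement (a baseline value, a typical
thickness, a full-scale signal), so ``noise_sd = 0`` silences every
generator at once and null configurations propagate to exactly-zero
downstream estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community_profiles import AbundanceTable
from .donor_selection import DEFAULT_DIRECTIONS, METABOLIC_PARAMETERS

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gen_cohort",
    "gen_paired_communities",
    "gen_bead_cloud",
    "gen_mouse_bead_images",
    "gen_mucus_experiment",
    "gen_assay_plate",
    "gen_metabolite_table",
    "bead_lambda_for_fraction",
]

# fixed stream ids; append-only so new generators never shift old streams
_STREAMS = {
    "responders": 0,
    "cohort": 1,
    "tree": 2,
    "communities": 3,
    "beads": 4,
    "mucus": 5,
    "assay": 6,
    "metabolites": 7,
}

# plausible middle-aged baseline means and between-subject SDs
_BASELINES = {
    "waist_to_hip_ratio": (0.95, 0.07),
    "body_mass_index": (28.5, 3.5),
    "free_fat_mass": (55.0, 8.0),
    "cholesterol": (5.4, 0.9),
    "triglycerides": (1.6, 0.5),
    "glucose": (5.5, 0.5),
}


@dataclass
class SimConfig:
    """Study conditions for all generators.

    Scale parameters are relative unless a unit is given; see the module
    docstring for how ``noise_sd`` is interpreted per generator.
    """

    seed: int = 0
    n_participants: int = 67
    n_responders: int = 5
    responder_effect: float = 0.10  # mean improvement, fraction of baseline
    n_taxa: int = 60
    n_samples_per_group: int = 8
    shift_scale: float = 0.5  # log-intensity displacement SD pre -> post
    bead_lambda: float = 30.0  # mean penetration depth, um
    bead_surface_height: float = 120.0  # mucus surface above epithelium, um
    noise_sd: float = 0.05
    # generator-specific knobs
    responder_shift_bonus: float = 1.0  # responders shift (1 + bonus) x more
    sequencing_depth: int = 10000
    # fraction of beads resting at the mucus surface; large enough that the
    # surface accumulation is the densest histogram band, the premise of the
    # mode-based surface definition
    bead_surface_weight: float = 0.30
    bead_surface_jitter_um: float = 1.5
    growth_rates: dict = field(
        default_factory=lambda: {"chow": 2.0, "wsd": 1.0}
    )
    typical_thickness_um: float = 100.0
    assay_slope: float = 0.005  # signal AU per uM 4-NP
    assay_intercept: float = 0.05
    assay_top_standard_um: float = 200.0
    assay_dilution_steps: int = 7
    assay_time_min: float = 45.0
    assay_protein_mg: float = 0.01

    def __post_init__(self):
        if self.n_responders > self.n_participants:
            raise ValueError("n_responders cannot exceed n_participants")
        for name in (
            "responder_effect", "shift_scale", "bead_lambda",
            "bead_surface_height", "noise_sd", "responder_shift_bonus",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if not 0 <= self.bead_surface_weight < 1:
            raise ValueError("bead_surface_weight must lie in [0, 1)")
        if self.assay_dilution_steps < 4:
            raise ValueError("need >= 4 dilution steps")

    def rng(self, stream: str, extra: int = 0) -> np.random.Generator:
        ss = np.random.SeedSequence([int(self.seed), _STREAMS[stream], extra])
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream stage."""

    responder_ids: tuple = ()
    fraction_within_zone: float | None = None  # per bead image
    group_growth_rates: dict = field(default_factory=dict)
    planted_fold_changes: dict = field(default_factory=dict)
    shift_sd: dict = field(default_factory=dict)  # participant -> log-SD
    curve: dict = field(default_factory=dict)  # slope/intercept/activities

    def to_dict(self) -> dict:
        d = asdict(self)
        d["responder_ids"] = list(self.responder_ids)
        return d


def _participant_ids(n: int) -> list[str]:
    return [f"P{i:03d}" for i in range(1, n + 1)]


def _responders(config: SimConfig) -> tuple[str, ...]:
    ids = _participant_ids(config.n_participants)
    rng = config.rng("responders")
    chosen = rng.choice(config.n_participants, size=config.n_responders,
                        replace=False)
    return tuple(sorted(ids[i] for i in chosen))


def gen_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Paired pre/post metabolic panel with a planted responder subset.

    Responders improve by ``responder_effect`` x baseline (in the direction
    that counts as improvement for each parameter) plus noise; everyone
    else changes by zero-mean noise of SD ``noise_sd`` x baseline.
    """
    ids = _participant_ids(config.n_participants)
    responders = set(_responders(config))
    rng = config.rng("cohort")
    rows = {}
    sexes = rng.choice(["m", "f"], size=len(ids))
    for pid, sex in zip(ids, sexes):
        row = {"sex": sex}
        is_resp = pid in responders
        for param in METABOLIC_PARAMETERS:
            mu, sd = _BASELINES[param]
            # physiological values are positive; clip rare low tails
            pre = max(rng.normal(mu, sd), 0.2 * mu)
            effect = config.responder_effect * pre if is_resp else 0.0
            noise = rng.normal(0.0, config.noise_sd * pre) if config.noise_sd else 0.0
            # direction +1 means decrease-is-improvement
            post = pre - DEFAULT_DIRECTIONS[param] * effect + noise
            row[f"{param}_pre"] = pre
            row[f"{param}_post"] = post
        rows[pid] = row
    cohort = pd.DataFrame.from_dict(rows, orient="index")
    cohort.index.name = "participant_id"
    return cohort, GroundTruth(responder_ids=tuple(sorted(responders)))


def _random_bifurcating_tree(n_taxa: int, rng: np.random.Generator) -> TreeNode:
    """Random rooted bifurcating tree with exponential branch lengths."""
    nodes = [TreeNode(name=f"T{i:03d}") for i in range(1, n_taxa + 1)]
    for node in nodes:
        node.length = float(rng.exponential(0.1)) + 1e-6
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(0.1)) + 1e-6
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def gen_paired_communities(
    config: SimConfig,
) -> tuple[AbundanceTable, TreeNode, GroundTruth]:
    """Paired pre/post gut communities on a shared random phylogeny.

    Per-taxon log-normal baseline intensities are shared across the cohort
    with individual jitter; the post sample displaces each taxon's log
    intensity by N(0, s_p) with s_p = shift_scale x (1 + bonus) for
    responders and shift_scale otherwise.  Counts are Poisson draws of the
    intensity proportions at the configured sequencing depth; a participant
    with zero displacement re-emits the identical pre counts, so a null
    configuration yields exactly-zero pre/post distances.
    """
    tree = _random_bifurcating_tree(config.n_taxa, config.rng("tree"))
    taxa = [t.name for t in tree.tips()]
    ids = _participant_ids(config.n_participants)
    responders = set(_responders(config))
    rng = config.rng("communities")

    base_log = rng.normal(0.0, 1.5, size=config.n_taxa)
    counts = {}
    meta = {}
    shift_sd = {}
    for pid in ids:
        jitter = rng.normal(0.0, 0.3, size=config.n_taxa)
        pre_log = base_log + jitter
        s = config.shift_scale * (
            1.0 + (config.responder_shift_bonus if pid in responders else 0.0)
        )
        shift_sd[pid] = s
        if s > 0:
            # random direction, deterministic magnitude: the displacement is
            # exactly proportional to the participant's planted shift scale
            direction = rng.normal(0.0, 1.0, size=config.n_taxa)
            direction /= np.linalg.norm(direction)
            displacement = s * math.sqrt(config.n_taxa) * direction
        else:
            displacement = 0.0
        post_log = pre_log + displacement
        p_pre = np.exp(pre_log)
        p_pre /= p_pre.sum()
        pre_counts = rng.poisson(config.sequencing_depth * p_pre)
        if np.isscalar(displacement) or not np.any(displacement):
            post_counts = pre_counts.copy()
        else:
            p_post = np.exp(post_log)
            p_post /= p_post.sum()
            post_counts = rng.poisson(config.sequencing_depth * p_post)
        counts[f"{pid}_pre"] = pre_counts
        counts[f"{pid}_post"] = post_counts
        meta[f"{pid}_pre"] = "pre"
        meta[f"{pid}_post"] = "post"
    frame = pd.DataFrame.from_dict(counts, orient="index", dtype=np.int64)
    frame.columns = taxa
    table = AbundanceTable(frame, sample_meta=meta)
    truth = GroundTruth(
        responder_ids=tuple(sorted(responders)), shift_sd=shift_sd
    )
    return table, tree, truth


def bead_lambda_for_fraction(
    fraction: float,
    surface_height: float = 120.0,
    zone_um: float = 10.0,
) -> float:
    """Penetration-depth scale whose expected fraction of penetrating beads
    within ``zone_um`` equals ``fraction``.

    Inverts the CDF of the exponential depth law truncated at the mucus
    surface (beads of the surface-accumulation mode are not penetrating
    beads and do not enter the fraction).
    """
    from scipy.optimize import brentq

    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")

    def f(lam):
        return (1 - math.exp(-zone_um / lam)) / (
            1 - math.exp(-surface_height / lam)
        ) - fraction

    return float(brentq(f, 1e-3, 1e4))


def gen_bead_cloud(
    config: SimConfig, n_beads: int, image: int = 0, mouse_id: str = "M1"
):
    """One bead-cloud image over a tilted-plane epithelium.

    Bead height above the epithelium follows an exponential(bead_lambda)
    law truncated at the mucus surface, mixed with a dense mode just below
    the surface (weight ``bead_surface_weight``) where washed-on beads
    accumulate.  Ground truth records the realized fraction of penetrating
    (non-surface-mode) beads within 10 um of the epithelium - the quantity
    the penetrability estimator is built to recover, since surface-resting
    beads are excluded from its denominator.
    """
    from .mucus_function import BeadCloud

    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = config.rng("beads", extra=image)
    H = config.bead_surface_height
    lam = config.bead_lambda
    plane = (0.02, -0.015, 10.0)  # gently tilted epithelium
    x = rng.uniform(0.0, 200.0, size=n_beads)
    y = rng.uniform(0.0, 200.0, size=n_beads)
    at_surface = rng.random(n_beads) < config.bead_surface_weight
    u = rng.random(n_beads)
    if lam > 0:
        depth = -lam * np.log1p(-u * (1.0 - math.exp(-H / lam)))
    else:
        depth = np.zeros(n_beads)
    jitter = np.abs(rng.normal(0.0, config.bead_surface_jitter_um, size=n_beads))
    d = np.where(at_surface, np.clip(H - jitter, 0.0, H), depth)
    a, b, c = plane
    z = a * x + b * y + c + d
    beads = pd.DataFrame({"x_um": x, "y_um": y, "z_um": z})
    cloud = BeadCloud(
        image_id=f"{mouse_id}_img{image}", mouse_id=mouse_id,
        beads=beads, epithelium=plane,
    )
    penetrating = d[~at_surface]
    realized = float(np.mean(penetrating <= 10.0)) if len(penetrating) else float("nan")
    return cloud, GroundTruth(fraction_within_zone=realized)


def gen_mouse_bead_images(
    config: SimConfig, n_images: int = 3, n_beads: int = 750,
    mouse_id: str = "M1", image_offset: int = 0,
):
    """Several images for one mouse; returns (clouds, truths)."""
    clouds, truths = [], []
    for i in range(n_images):
        c, t = gen_bead_cloud(
            config, n_beads, image=image_offset + i, mouse_id=mouse_id
        )
        clouds.append(c)
        truths.append(t)
    return clouds, truths


def gen_mucus_experiment(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Timed thickness measurements: 5 sites x 2 timepoints per mouse.

    thickness(45) = thickness(0) + 45 x group rate + noise, with noise SD
    ``noise_sd`` x ``typical_thickness_um`` per site.
    """
    if not config.growth_rates:
        raise ValueError("growth_rates must define at least one group")
    rng = config.rng("mucus")
    rows = []
    sd = config.noise_sd * config.typical_thickness_um
    for group, rate in config.growth_rates.items():
        for m in range(1, config.n_samples_per_group + 1):
            mouse = f"{group}_m{m:02d}"
            for site in range(1, 6):
                t0 = rng.normal(80.0, 5.0)
                noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                t45 = t0 + 45.0 * rate + noise
                rows.append((mouse, group, site, 0.0, t0))
                rows.append((mouse, group, site, 45.0, t45))
    frame = pd.DataFrame(
        rows, columns=["mouse_id", "group", "site", "time_min", "thickness_um"]
    )
    return frame, GroundTruth(group_growth_rates=dict(config.growth_rates))


def gen_assay_plate(
    config: SimConfig, activities: dict | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Plate of standards (serial two-fold dilution) and duplicate unknowns.

    Standards follow signal = a x conc + b + noise; unknown signals encode
    planted activities (uM/min/mg) through the incubation time and protein
    mass of the assay.  Noise SD is ``noise_sd`` x full-scale signal.
    """
    if activities is None:
        activities = {
            "beta-glucosidase": 120.0,
            "beta-xylosidase": 60.0,
            "alpha-galactosidase": 30.0,
            "beta-N-acetyl-glucosaminidase": 45.0,
            "alpha-fucosidase": 15.0,
            "sialidase": 80.0,
        }
    rng = config.rng("assay")
    a, b = config.assay_slope, config.assay_intercept
    full_scale = a * config.assay_top_standard_um
    sd = config.noise_sd * full_scale
    rows = []
    conc = config.assay_top_standard_um
    for step in range(config.assay_dilution_steps):
        noise = rng.normal(0.0, sd) if sd > 0 else 0.0
        rows.append((f"std{step}", "standard", "standard", conc,
                     a * conc + b + noise))
        conc /= 2.0
    rows.append(("blank", "blank", "blank", 0.0, b))
    for enzyme, act in activities.items():
        released = act * config.assay_time_min * config.assay_protein_mg
        for rep in range(2):
            noise = rng.normal(0.0, sd) if sd > 0 else 0.0
            rows.append((f"{enzyme}_r{rep}", enzyme, "sample", np.nan,
                         a * released + b + noise))
    plate = pd.DataFrame(
        rows, columns=["well", "analyte", "role", "x_value", "signal"]
    )
    truth = GroundTruth(
        curve={"slope": a, "intercept": b, "activities": dict(activities)}
    )
    return plate, truth


def gen_metabolite_table(
    config: SimConfig,
    n_metabolites: int = 30,
    planted_fc: dict | None = None,
    n_per_group: int | None = None,
    missing_rate: float = 0.05,
):
    """Two-group metabolite peak-area table with planted fold changes.

    Group "treated" multiplies the planted metabolites' concentration by
    the given fold change; peak area = concentration x sample weight, so
    weight normalization recovers the planted structure.  Missing peaks
    are planted completely at random at ``missing_rate``.

    Returns (peaks, weights, groups, GroundTruth).
    """
    if planted_fc is None:
        planted_fc = {f"met{i:02d}": 3.0 for i in range(1, 6)}
    n_per_group = n_per_group or config.n_samples_per_group
    rng = config.rng("metabolites")
    mets = [f"met{i:02d}" for i in range(1, n_metabolites + 1)]
    unknown = set(planted_fc) - set(mets)
    if unknown:
        raise ValueError(f"planted metabolites outside table: {sorted(unknown)}")
    samples = [f"ctl{i:02d}" for i in range(1, n_per_group + 1)] + [
        f"trt{i:02d}" for i in range(1, n_per_group + 1)
    ]
    groups = pd.Series(
        ["control"] * n_per_group + ["treated"] * n_per_group, index=samples
    )
    base = rng.lognormal(mean=10.0, sigma=1.0, size=n_metabolites)
    weights = pd.Series(rng.uniform(30.0, 50.0, size=len(samples)), index=samples)
    data = np.empty((len(samples), n_metabolites))
    for j, met in enumerate(mets):
        for i, s in enumerate(samples):
            conc = base[j]
            if groups[s] == "treated" and met in planted_fc:
                conc *= planted_fc[met]
            if config.noise_sd > 0:
                conc *= math.exp(rng.normal(0.0, config.noise_sd))
            data[i, j] = conc * weights[s]
    peaks = pd.DataFrame(data, index=samples, columns=mets)
    if missing_rate > 0:
        mask = rng.random(peaks.shape) < missing_rate
        peaks = peaks.mask(mask)
    truth = GroundTruth(planted_fold_changes=dict(planted_fc))
    return peaks, weights, groups, truth
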