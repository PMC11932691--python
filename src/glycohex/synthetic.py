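"""Synthetic cohort generators with known ground truth for every pipeline input.

Every generator is a pure function of (config, seed) so downstream stages can
be tested end-to-end without any external data. The defaults reproduce the
study conditions of the CRC discovery and validation cohorts:

* tissue / PBMC discovery cohort: 7 donors per CRC stage I-IV plus 8
  controls (36 samples), multiplexed over four TMT-10plex batches that share
  a pooled reference in the 126 channel;
* group-level glycome profiles with stage-dependent paucimannose elevation
  (tissue: NAT 6.7% -> stage I-IV 13.5-15.4%; PBMC: control 14.9% ->
  stage I-IV 19.5-27.1%), with the fucosylated M2F + M3F species carrying
  ~65% of the paucimannosidic signal;
* fluorometric plate assays with a linear 4-MU response plus Gaussian read
  noise;
* a 380-donor plasma cohort (302 CRC + 78 healthy) with
  proportional-hazards survival structure, an age confounder, and
  administrative censoring at 5 years.

Sample-level variation of glycome class shares uses logistic-normal noise
(softmax of a Gaussian perturbation of log mean shares): dispersion 0 is an
exact pass-through of the group means, and shares renormalize to 1 by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats as sps

from .glycan_model import GlycanClass

__all__ = [
    "CohortDesign",
    "GlycomeProfile",
    "SurvivalSimConfig",
    "TMT10_CHANNELS",
    "DEFAULT_SPECIES",
    "tissue_profile",
    "pbmc_profile",
    "default_profiles",
    "generate_glycome_table",
    "generate_glycopsm_table",
    "generate_annotation_sets",
    "generate_plate_readings",
    "generate_survival_cohort",
    "generate_correlated_pairs",
    "calibrate_baseline_hazard",
]

#: TMT-10plex reporter channels in mass order; 126 is the pooled reference.
TMT10_CHANNELS = ("126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131")


@dataclass(frozen=True)
class CohortDesign:
    """Sample groups and TMT batch layout of the discovery cohort.

    The default is the 36-sample design: 7 donors per CRC stage I-IV plus 8
    controls, spread over four TMT-10plex batches. Each batch carries the
    pooled reference in its first channel, leaving nine sample channels, and
    every batch contains at least one sample of each stage and one control.
    """

    groups: tuple[tuple[str, int], ...] = (
        ("control", 8),
        ("I", 7),
        ("II", 7),
        ("III", 7),
        ("IV", 7),
    )
    plexes: int = 4
    ref_channel: str = "126"

    def __post_init__(self) -> None:
        if self.plexes < 1:
            raise ValueError("plexes must be >= 1")
        for label, n in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r} has non-positive size {n}")
        n_slots = self.plexes * (len(TMT10_CHANNELS) - 1)
        if self.n_samples > n_slots:
            raise ValueError(
                f"{self.n_samples} samples exceed {n_slots} available sample channels"
            )
        # round-robin assignment guarantees each plex sees every group when
        # every group has at least `plexes` members; smaller groups violate
        # the balanced-batch contract
        for label, n in self.groups:
            if n < self.plexes:
                raise ValueError(
                    f"group {label!r} (n={n}) cannot cover all {self.plexes} plexes"
                )

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups)

    def sample_table(self) -> pd.DataFrame:
        """One row per sample: id, group, plex, channel.

        Samples of each group are dealt round-robin across plexes with a
        per-group starting offset (so batch loads stay balanced), then plex
        channels are filled in mass order (skipping the reference).
        """
        rows = []
        for g, (label, n) in enumerate(self.groups):
            for i in range(n):
                rows.append({"sample_id": f"{label}_{i + 1:02d}", "group": label,
                             "plex": (i + g) % self.plexes + 1})
        df = pd.DataFrame(rows)
        sample_channels = [c for c in TMT10_CHANNELS if c != self.ref_channel]
        chans = []
        counters = {p: 0 for p in range(1, self.plexes + 1)}
        for plex in df["plex"]:
            chans.append(sample_channels[counters[plex]])
            counters[plex] += 1
        df["channel"] = chans
        return df


# ---------------------------------------------------------------------------
# glycome profiles
# ---------------------------------------------------------------------------

#: Species universe used by the default profiles: label -> (composition
#: string, glycan class). Classes follow the default rule table.
DEFAULT_SPECIES: dict[str, tuple[str, GlycanClass]] = {
    "M1": ("Hex1HexNAc2", GlycanClass.PAUCIMANNOSE),
    "M1F": ("Hex1HexNAc2dHex1", GlycanClass.PAUCIMANNOSE),
    "M2": ("Hex2HexNAc2", GlycanClass.PAUCIMANNOSE),
    "M2F": ("Hex2HexNAc2dHex1", GlycanClass.PAUCIMANNOSE),
    "M3": ("Hex3HexNAc2", GlycanClass.PAUCIMANNOSE),
    "M3F": ("Hex3HexNAc2dHex1", GlycanClass.PAUCIMANNOSE),
    "M0": ("HexNAc2", GlycanClass.CHITOBIOSE_CORE),
    "M0F": ("HexNAc2dHex1", GlycanClass.CHITOBIOSE_CORE),
    "GlcNAc1": ("HexNAc1", GlycanClass.CHITOBIOSE_CORE),
    "Man5": ("Hex5HexNAc2", GlycanClass.OLIGOMANNOSE),
    "Man6": ("Hex6HexNAc2", GlycanClass.OLIGOMANNOSE),
    "Man7": ("Hex7HexNAc2", GlycanClass.OLIGOMANNOSE),
    "Man8": ("Hex8HexNAc2", GlycanClass.OLIGOMANNOSE),
    "Man9": ("Hex9HexNAc2", GlycanClass.OLIGOMANNOSE),
    "Hybrid1": ("Hex5HexNAc3", GlycanClass.HYBRID),
    "Hybrid1S": ("Hex6HexNAc3NeuAc1", GlycanClass.HYBRID),
    "BiAntF": ("Hex5HexNAc4dHex1", GlycanClass.COMPLEX),
    "BiAntFS2": ("Hex5HexNAc4dHex1NeuAc2", GlycanClass.COMPLEX),
    "TriAntFS": ("Hex6HexNAc5dHex1NeuAc1", GlycanClass.COMPLEX),
}

_DEFAULT_SPECIES_WEIGHTS: dict[GlycanClass, dict[str, float]] = {
    GlycanClass.PAUCIMANNOSE: {
        "M1": 0.05, "M1F": 0.05, "M2": 0.10, "M2F": 0.30, "M3": 0.15, "M3F": 0.35,
    },
    GlycanClass.CHITOBIOSE_CORE: {"M0": 0.6, "M0F": 0.2, "GlcNAc1": 0.2},
    GlycanClass.OLIGOMANNOSE: {
        "Man5": 0.30, "Man6": 0.20, "Man7": 0.15, "Man8": 0.15, "Man9": 0.20,
    },
    GlycanClass.HYBRID: {"Hybrid1": 0.6, "Hybrid1S": 0.4},
    GlycanClass.COMPLEX: {"BiAntF": 0.35, "BiAntFS2": 0.35, "TriAntFS": 0.30},
}

# relative proportions of the non-paucimannose glycome; scaled to 1 - pauci
_NON_PAUCI_BASE = {
    GlycanClass.CHITOBIOSE_CORE: 0.03,
    GlycanClass.OLIGOMANNOSE: 0.26,
    GlycanClass.HYBRID: 0.09,
    GlycanClass.COMPLEX: 0.62,
}

#: Group-mean paucimannose fraction of the total glycome.
TISSUE_PAUCI_SHARE = {"control": 0.067, "I": 0.135, "II": 0.141, "III": 0.148, "IV": 0.154}
PBMC_PAUCI_SHARE = {"control": 0.149, "I": 0.195, "II": 0.220, "III": 0.246, "IV": 0.271}


@dataclass(frozen=True)
class GlycomeProfile:
    """Group-level glycome composition: class shares plus within-class weights.

    ``class_shares`` are fractions of the total glycome summing to 1;
    ``species_weights`` distribute each class share over its species and sum
    to 1 within each class. ``dispersion`` is the SD of the logistic-normal
    perturbation applied per sample (0 = exact group means).
    """

    class_shares: Mapping[GlycanClass, float]
    species_weights: Mapping[GlycanClass, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_SPECIES_WEIGHTS
    )
    dispersion: float = 0.15

    def __post_init__(self) -> None:
        total = sum(self.class_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class shares must sum to 1, got {total}")
        if any(s < 0 or s > 1 for s in self.class_shares.values()):
            raise ValueError("class shares must lie in [0, 1]")
        for cls, weights in self.species_weights.items():
            wsum = sum(weights.values())
            if abs(wsum - 1.0) > 1e-9:
                raise ValueError(f"species weights for {cls} sum to {wsum}, expected 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _profile_from_pauci(pauci: float, dispersion: float) -> GlycomeProfile:
    shares = {GlycanClass.PAUCIMANNOSE: pauci}
    rest = 1.0 - pauci
    for cls, w in _NON_PAUCI_BASE.items():
        shares[cls] = rest * w
    return GlycomeProfile(class_shares=shares, dispersion=dispersion)


def tissue_profile(group: str, dispersion: float = 0.15) -> GlycomeProfile:
    """Tissue glycome profile for a cohort group ('control' = NAT)."""
    return _profile_from_pauci(TISSUE_PAUCI_SHARE[group], dispersion)


def pbmc_profile(group: str, dispersion: float = 0.15) -> GlycomeProfile:
    """PBMC glycome profile for a cohort group ('control' = healthy donor)."""
    return _profile_from_pauci(PBMC_PAUCI_SHARE[group], dispersion)


def default_profiles(
    design: CohortDesign, specimen: str = "tissue", dispersion: float = 0.15
) -> dict[str, GlycomeProfile]:
    """Per-group default profiles for a design ('tissue' or 'pbmc')."""
    fn = {"tissue": tissue_profile, "pbmc": pbmc_profile}[specimen]
    return {label: fn(label, dispersion) for label, _ in design.groups}


def generate_glycome_table(
    design: CohortDesign,
    profiles: Mapping[str, GlycomeProfile],
    seed: int,
) -> pd.DataFrame:
    """Per-sample relative glycan abundances (rows = species, cols = samples).

    For each sample the class shares are drawn around the group means with
    logistic-normal noise and distributed over species by the profile's
    within-class weights; every column sums to 1. The returned frame carries
    a ``composition`` column ahead of the sample columns.
    """
    rng = np.random.default_rng(seed)
    samples = design.sample_table()
    missing = set(samples["group"]) - set(profiles)
    if missing:
        raise ValueError(f"no profile for groups: {sorted(missing)}")

    species = list(DEFAULT_SPECIES)
    data = {}
    for _, row in samples.iterrows():
        prof = profiles[row["group"]]
        classes = [c for c in prof.class_shares if prof.class_shares[c] > 0]
        means = np.array([prof.class_shares[c] for c in classes])
        if prof.dispersion > 0:
            logits = np.log(means) + prof.dispersion * rng.standard_normal(len(classes))
            shares = np.exp(logits - logits.max())
            shares /= shares.sum()
        else:
            shares = means / means.sum()
        abund = dict.fromkeys(species, 0.0)
        for cls, share in zip(classes, shares):
            for sp, w in prof.species_weights.get(cls, {}).items():
                abund[sp] += share * w
        data[row["sample_id"]] = [abund[sp] for sp in species]

    out = pd.DataFrame(data, index=pd.Index(species, name="species"))
    out.insert(0, "composition", [DEFAULT_SPECIES[sp][0] for sp in species])
    return out


# ---------------------------------------------------------------------------
# glycoPSM tables
# ---------------------------------------------------------------------------

def generate_glycopsm_table(
    design: CohortDesign,
    truth: Mapping[tuple[str, int, str], Mapping[str, float] | float],
    seed: int,
    max_psms_per_feature: int = 5,
    decoy_fraction: float = 0.0,
    noise_cv: float = 0.0,
    channel_bias_sd: float = 0.0,
    plex_factor_sd: float = 0.0,
    base_intensity: float = 1e6,
) -> pd.DataFrame:
    """Simulate a glycoPSM reporter-intensity table from a feature truth map.

    ``truth`` maps (accession, site, composition) -> per-sample relative
    abundance: either a scalar (same for all samples) or a mapping keyed by
    sample id or group label. Each feature spawns 1..max_psms_per_feature
    PSMs whose channel intensities sum to the feature totals (exactly at
    ``noise_cv`` 0). Raw intensities include per-plex multiplicative batch
    factors and per-channel biases (lognormal with the given SDs); the
    reference channel of every plex carries the pooled mean across all
    samples, so fold changes versus the pool are the recoverable truth.

    A ``decoy_fraction`` of additional PSMs receives PEP2D >= 0.001 (to be
    removed by filtering); genuine PSMs receive PEP2D < 0.0005.
    """
    if not truth:
        raise ValueError("truth map must contain at least one feature")
    if not 0 <= decoy_fraction < 1:
        raise ValueError("decoy_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    samples = design.sample_table()

    def fc_for(spec, row) -> float:
        if isinstance(spec, Mapping):
            if row["sample_id"] in spec:
                return float(spec[row["sample_id"]])
            return float(spec[row["group"]])
        return float(spec)

    plex_factors = {
        p: math.exp(plex_factor_sd * rng.standard_normal()) if plex_factor_sd else 1.0
        for p in range(1, design.plexes + 1)
    }
    channel_bias = {
        (p, c): math.exp(channel_bias_sd * rng.standard_normal()) if channel_bias_sd else 1.0
        for p in range(1, design.plexes + 1)
        for c in TMT10_CHANNELS
    }

    rows = []
    spectrum = 0
    for (accession, site, composition), spec in truth.items():
        fcs = {r["sample_id"]: fc_for(spec, r) for _, r in samples.iterrows()}
        pooled = float(np.mean(list(fcs.values())))
        base = base_intensity * math.exp(0.5 * rng.standard_normal())
        for plex in range(1, design.plexes + 1):
            in_plex = samples[samples["plex"] == plex]
            channel_truth = {design.ref_channel: base * pooled}
            for _, r in in_plex.iterrows():
                channel_truth[r["channel"]] = base * fcs[r["sample_id"]]
            n_psms = int(rng.integers(1, max_psms_per_feature + 1))
            split = rng.dirichlet(np.ones(n_psms)) if n_psms > 1 else np.array([1.0])
            for j in range(n_psms):
                spectrum += 1
                rec = {
                    "spectrum_id": f"scan_{spectrum:06d}",
                    "accession": accession,
                    "site": site,
                    "composition": composition,
                    "pep2d": float(rng.uniform(0, 5e-4)),
                    "plex": plex,
                }
                for ch in TMT10_CHANNELS:
                    val = channel_truth.get(ch, 0.0) * split[j]
                    val *= plex_factors[plex] * channel_bias[(plex, ch)]
                    if noise_cv > 0:
                        val *= math.exp(noise_cv * rng.standard_normal())
                    rec[ch] = val
                rows.append(rec)

    n_true = len(rows)
    if decoy_fraction > 0:
        n_decoys = int(round(n_true * decoy_fraction / (1 - decoy_fraction)))
        for d in range(n_decoys):
            spectrum += 1
            rec = {
                "spectrum_id": f"scan_{spectrum:06d}",
                "accession": f"DECOY_{d:04d}",
                "site": int(rng.integers(1, 1000)),
                "composition": "Hex5HexNAc4",
                "pep2d": float(rng.uniform(1e-3, 0.5)),
                "plex": int(rng.integers(1, design.plexes + 1)),
            }
            for ch in TMT10_CHANNELS:
                rec[ch] = float(rng.uniform(0, base_intensity / 10))
            rows.append(rec)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation sets
# ---------------------------------------------------------------------------

#: Default HPA-style set sizes (tissue bone marrow; blood immune lineages).
DEFAULT_SET_SIZES = {
    "bone_marrow": 534,
    "nk_cell": 114,
    "b_cell": 141,
    "t_cell": 262,
    "monocyte": 201,
}


def generate_annotation_sets(
    seed: int,
    sizes: Mapping[str, int] = DEFAULT_SET_SIZES,
    shared: Optional[Mapping[tuple[str, str], int]] = None,
) -> dict[str, frozenset[str]]:
    """Synthetic protein->cell-origin annotation sets with controlled overlap.

    Sets are pairwise disjoint unless ``shared`` plants a given number of
    common accessions between named pairs. Accessions are synthetic
    UniProt-style identifiers; membership is reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    counter = 0

    def new_accessions(n: int) -> list[str]:
        nonlocal counter
        accs = [f"P{counter + i:05d}" for i in range(n)]
        counter += n
        return accs

    sets: dict[str, set[str]] = {name: set() for name in sizes}
    for (a, b), k in (shared or {}).items():
        common = new_accessions(k)
        sets[a].update(common)
        sets[b].update(common)
    for name, size in sizes.items():
        deficit = size - len(sets[name])
        if deficit < 0:
            raise ValueError(f"planted overlaps exceed size of set {name!r}")
        sets[name].update(new_accessions(deficit))
    # deterministic shuffle so accession order carries no information
    return {name: frozenset(members) for name, members in sets.items()}


# ---------------------------------------------------------------------------
# plate assays
# ---------------------------------------------------------------------------

#: 4-MU calibration points (uM final) used by default plates.
DEFAULT_STANDARD_CONCENTRATIONS = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0)


def generate_plate_readings(
    slope: float,
    intercept: float,
    sample_activities: Mapping[str, tuple[float, float]],
    noise_sd: float,
    seed: int,
    standard_concentrations: Sequence[float] = DEFAULT_STANDARD_CONCENTRATIONS,
    incubation_min: float = 30.0,
    input_amount: float = 2.0,
    n_replicates: int = 3,
    n_blanks: int = 3,
    control_ids: Sequence[str] = (),
) -> pd.DataFrame:
    """Simulate one fluorometric Hex plate (standards, blanks, MUG/MUGS wells).

    Standards follow fluorescence = slope * concentration + intercept +
    Gaussian noise. Sample wells encode true activities (4-MU amount per
    minute per input amount): the planted product for activity a is
    a * incubation_min * input_amount, converted to fluorescence through the
    same line. Technical replicates are emitted for both substrates; blanks
    read intercept + noise.
    """
    if slope <= 0:
        raise ValueError("standard-curve slope must be positive")
    if len(set(standard_concentrations)) < 3:
        raise ValueError("need at least 3 distinct standard concentrations")
    rng = np.random.default_rng(seed)

    def noise() -> float:
        return float(noise_sd * rng.standard_normal()) if noise_sd > 0 else 0.0

    rows = []
    well = 0
    for conc in standard_concentrations:
        well += 1
        rows.append(
            {"well": f"W{well:03d}", "role": "standard", "sample_id": "", "substrate": "",
             "replicate": 1, "concentration": conc,
             "fluorescence": slope * conc + intercept + noise()}
        )
    for i in range(n_blanks):
        well += 1
        rows.append(
            {"well": f"W{well:03d}", "role": "blank", "sample_id": "", "substrate": "",
             "replicate": i + 1, "concentration": np.nan,
             "fluorescence": intercept + noise()}
        )
    for sample_id, (mug, mugs) in sample_activities.items():
        for substrate, activity in (("MUG", mug), ("MUGS", mugs)):
            for rep in range(1, n_replicates + 1):
                well += 1
                product = activity * incubation_min * input_amount
                rows.append(
                    {"well": f"W{well:03d}", "role": "sample", "sample_id": sample_id,
                     "substrate": substrate, "replicate": rep, "concentration": np.nan,
                     "fluorescence": slope * product + intercept + noise()}
                )
    df = pd.DataFrame(rows)
    df.attrs["incubation_min"] = incubation_min
    df.attrs["input_amount"] = input_amount
    df.attrs["control_ids"] = list(control_ids)
    return df


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalSimConfig:
    """Proportional-hazards plasma-cohort simulator configuration.

    Defaults emulate the 380-donor validation cohort: 302 CRC patients
    (whose survivor/nonsurvivor split emerges from the hazard model at an
    expected 5-year event fraction of 87/302) and 78 healthy controls
    carrying activity measurements only. Age is in years, activity in
    relative activity units. ``baseline_hazard`` of ``None`` means
    "calibrate so the expected event fraction matches ``event_fraction``".
    """

    n_crc: int = 302
    n_healthy: int = 78
    age_mean: float = 63.9
    age_sd: float = 12.7
    activity_mean: float = 1.0
    activity_sd: float = 0.3
    age_activity_corr: float = 0.2
    beta_activity: float = math.log(2.04)
    beta_age: float = math.log(1.03)
    baseline_hazard: Optional[float] = None
    event_fraction: float = 87.0 / 302.0
    censor_years: float = 5.0
    healthy_activity_mean: float = 0.81
    healthy_activity_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.age_sd <= 0 or self.activity_sd <= 0 or self.healthy_activity_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not -1 < self.age_activity_corr < 1:
            raise ValueError("age-activity correlation must lie in (-1, 1)")
        if self.censor_years <= 0:
            raise ValueError("censoring time must be positive")
        if not 0 < self.event_fraction < 1:
            raise ValueError("event_fraction must lie in (0, 1)")
        if self.baseline_hazard is not None and self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")


def calibrate_baseline_hazard(cfg: SurvivalSimConfig) -> float:
    """Baseline hazard h0 giving the configured expected 5-year event fraction.

    The linear predictor eta = beta_age*age + beta_act*activity is normal
    under the bivariate-normal covariate model, so the expected event
    probability E[1 - exp(-T h0 e^eta)] is a 1-D Gaussian integral, solved
    for h0 by bracketing.
    """
    mu = cfg.beta_age * cfg.age_mean + cfg.beta_activity * cfg.activity_mean
    var = (
        (cfg.beta_age * cfg.age_sd) ** 2
        + (cfg.beta_activity * cfg.activity_sd) ** 2
        + 2 * cfg.age_activity_corr * cfg.beta_age * cfg.beta_activity * cfg.age_sd * cfg.activity_sd
    )
    sd = math.sqrt(var)

    def event_prob(log_h0: float) -> float:
        def integrand(z: float) -> float:
            eta = mu + sd * z
            return (1.0 - math.exp(-cfg.censor_years * math.exp(log_h0 + eta))) * sps.norm.pdf(z)

        val, _ = integrate.quad(integrand, -8, 8)
        return val

    sol = optimize.brentq(
        lambda lh: event_prob(lh) - cfg.event_fraction, math.log(1e-12), math.log(1e4)
    )
    return math.exp(sol)


def generate_survival_cohort(cfg: SurvivalSimConfig, seed: int) -> pd.DataFrame:
    """Simulate the plasma cohort: id, group, age, activity, event, time.

    CRC donors draw (age, activity) from a bivariate normal; event times are
    exponential with hazard h0 * exp(beta_act*activity + beta_age*age) and
    administratively censored at ``censor_years``. Donors with an observed
    event are labeled ``nonsurvivor``, the rest ``survivor``. Healthy
    controls carry activity only (event/time are missing).
    """
    rng = np.random.default_rng(seed)
    h0 = cfg.baseline_hazard if cfg.baseline_hazard is not None else calibrate_baseline_hazard(cfg)

    cov = cfg.age_activity_corr * cfg.age_sd * cfg.activity_sd
    age_act = rng.multivariate_normal(
        [cfg.age_mean, cfg.activity_mean],
        [[cfg.age_sd**2, cov], [cov, cfg.activity_sd**2]],
        size=cfg.n_crc,
    )
    age, activity = age_act[:, 0], age_act[:, 1]
    hazard = h0 * np.exp(cfg.beta_activity * activity + cfg.beta_age * age)
    raw_t = rng.exponential(1.0 / hazard)
    event = (raw_t <= cfg.censor_years).astype(int)
    time = np.minimum(raw_t, cfg.censor_years)
    # guard against zero follow-up (astronomically unlikely, but time > 0 is a contract)
    time = np.maximum(time, 1e-9)

    crc = pd.DataFrame(
        {
            "donor_id": [f"CRC_{i + 1:03d}" for i in range(cfg.n_crc)],
            "group": np.where(event == 1, "nonsurvivor", "survivor"),
            "age": age,
            "activity": activity,
            "event": event,
            "time": time,
        }
    )
    healthy = pd.DataFrame(
        {
            "donor_id": [f"CTRL_{i + 1:03d}" for i in range(cfg.n_healthy)],
            "group": "healthy",
            "age": rng.normal(cfg.age_mean, cfg.age_sd, size=cfg.n_healthy),
            "activity": rng.normal(
                cfg.healthy_activity_mean, cfg.healthy_activity_sd, size=cfg.n_healthy
            ),
            "event": np.nan,
            "time": np.nan,
        }
    )
    return pd.concat([crc, healthy], ignore_index=True)


def generate_correlated_pairs(
    n: int, rho: float, seed: int, mean: tuple[float, float] = (0.0, 0.0),
    sd: tuple[float, float] = (1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate normal sample with population correlation ``rho``."""
    if not -1 <= rho <= 1:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    x = z[:, 0]
    y = rho * z[:, 0] + math.sqrt(max(0.0, 1 - rho * rho)) * z[:, 1]
    return mean[0] + sd[0] * x, mean[1] + sd[1] * y
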