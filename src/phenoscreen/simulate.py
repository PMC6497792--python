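"""Synthetic phenotype, time-course and qPCR data generators.

The generators mirror the statistical structure the analysis assumes:

* ``simulate_trait`` draws a balanced g x s x r table from the additive
  model  y_ijk = mu + env_j + G_i + GE_ij + e_ijk  with independent
  Gaussian genotype, genotype-by-environment and residual effects, so the
  true broad-sense heritability implied by a :class:`TraitSpec` is known
  in closed form and parameter recovery is quantifiable.
* ``simulate_population`` applies this per trait over a catalogue (the
  default catalogue encodes the 24-trait drought screen: a 16-genotype,
  two-watering-regime, three-replicate spring wheat panel), optionally
  injecting between-trait correlation through a shared genotype factor.
* ``simulate_timecourse`` emits fold-change trajectories over a 14-day
  progressive drought with three phases, with contrasting defaults for a
  tolerant genotype (early peroxisome proliferation, stable water
  status) and a susceptible one (late peroxisome surge, collapsing
  water status).
* ``simulate_qpcr`` generates raw Ct tables under the comparative-Ct
  model so the expression pipeline can be round-trip tested.

All randomness flows from an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import CatalogueError, ParameterError
from .io import (
    NON_STRESSED,
    STRESSED,
    PhenotypeTable,
    phenotype_table_from_frame,
    qpcr_table_from_frame,
)

PEROXISOME_GENES = (
    "TaPEX11-3",
    "TaPEX11-4",
    "TaPEX11-5",
    "TaFIS1A",
    "TaDRP3A",
    "TaDRP3B",
    "TaDRP5B",
)


@dataclass(frozen=True)
class TraitSpec:
    """Generative parameters of one trait.

    ``effect`` is the additive stressed shift of the population mean, so
    the implied stress-response index is ``effect / mu_ns * 100``.
    ``bounds`` clips simulated values; ``integer`` rounds them (ordinal
    rating scales).
    """

    trait: str
    mu_ns: float
    effect: float
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    bounds: tuple | None = None
    integer: bool = False

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ParameterError(f"trait {self.trait!r}: negative variance component")

    @property
    def mu_s(self) -> float:
        return self.mu_ns + self.effect

    @property
    def implied_index(self) -> float:
        """Stress-response index (percent) implied by the mean shift."""
        return self.effect / self.mu_ns * 100.0

    def true_heritability(self, s: int, r: int) -> float:
        """Closed-form broad-sense H (percent) for a g x s x r design."""
        denom = self.sigma2_g + self.sigma2_ge / s + self.sigma2_e / (s * r)
        return 100.0 * self.sigma2_g / denom if denom > 0 else 0.0


def _genotype_names(g: int) -> list:
    return [f"G{i + 1:02d}" for i in range(g)]


def _finish_values(values: np.ndarray, spec: TraitSpec) -> np.ndarray:
    if spec.bounds is not None:
        lo, hi = spec.bounds
        values = np.clip(
            values,
            -np.inf if lo is None else lo,
            np.inf if hi is None else hi,
        )
    if spec.integer:
        values = np.round(values)
    return values


def _trait_frame(
    spec: TraitSpec,
    g: int,
    s: int,
    r: int,
    rng: np.random.Generator,
    latent: np.ndarray | None = None,
    loading: float = 0.0,
) -> pd.DataFrame:
    if g < 2 or r < 2:
        raise ParameterError("need g >= 2 genotypes and r >= 2 replicates")
    if not 1 <= s <= 2:
        raise ParameterError("s must be 1 (non-stressed only) or 2")
    envs = [NON_STRESSED, STRESSED][:s]
    env_shift = {NON_STRESSED: 0.0, STRESSED: spec.effect}

    sg = np.sqrt(spec.sigma2_g)
    if latent is not None and loading != 0.0:
        unique = rng.standard_normal(g)
        G = sg * (loading * latent + np.sqrt(1.0 - loading**2) * unique)
    else:
        G = sg * rng.standard_normal(g)
    GE = np.sqrt(spec.sigma2_ge) * rng.standard_normal((g, s))
    e = np.sqrt(spec.sigma2_e) * rng.standard_normal((g, s, r))

    names = _genotype_names(g)
    rows = {
        "genotype": np.repeat(names, s * r),
        "environment": np.tile(np.repeat(envs, r), g),
        "replicate": np.tile(np.arange(1, r + 1), g * s),
        "trait": spec.trait,
    }
    values = (
        spec.mu_ns
        + np.array([env_shift[env] for env in envs])[None, :, None]
        + G[:, None, None]
        + GE[:, :, None]
        + e
    ).ravel()
    rows["value"] = _finish_values(values, spec)
    return pd.DataFrame(rows)


def simulate_trait(
    spec: TraitSpec, g: int = 16, s: int = 2, r: int = 3, seed: int = 0
) -> PhenotypeTable:
    """Simulate one trait's balanced g x s x r phenotype table."""
    rng = np.random.default_rng(seed)
    return phenotype_table_from_frame(_trait_frame(spec, g, s, r, rng))


def simulate_population(
    catalogue: list,
    g: int = 16,
    s: int = 2,
    r: int = 3,
    seed: int = 0,
    latent_loadings: dict | None = None,
) -> PhenotypeTable:
    """Simulate the full multi-trait population.

    Traits are independent by default.  ``latent_loadings`` maps trait
    name -> loading in [-1, 1] on a shared standard-normal genotype
    factor; traits with loading 1.0 share the same genetic ranking and
    their genotype-mean correlation approaches 1 as residual noise
    vanishes.
    """
    names = [spec.trait for spec in catalogue]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise CatalogueError(f"duplicate trait names in catalogue: {dupes}")
    if not catalogue:
        raise CatalogueError("catalogue is empty")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(catalogue) + 1)
    latent = np.random.default_rng(children[0]).standard_normal(g)
    loadings = latent_loadings or {}
    frames = [
        _trait_frame(
            spec,
            g,
            s,
            r,
            np.random.default_rng(child),
            latent=latent,
            loading=float(loadings.get(spec.trait, 0.0)),
        )
        for spec, child in zip(catalogue, children[1:])
    ]
    return phenotype_table_from_frame(pd.concat(frames, ignore_index=True))


def _spec_from_entry(entry: dict, split: dict) -> TraitSpec:
    sd_ns = float(entry.get("sd_ns", 0.0))
    sd_s = float(entry.get("sd_s", sd_ns))
    pooled = (sd_ns**2 + sd_s**2) / 2.0
    bounds = entry.get("bounds")
    return TraitSpec(
        trait=entry["trait"],
        mu_ns=float(entry["mu_ns"]),
        effect=float(entry["mu_s"]) - float(entry["mu_ns"]),
        sigma2_g=split["genetic"] * pooled,
        sigma2_ge=split["gxe"] * pooled,
        sigma2_e=split["residual"] * pooled,
        bounds=tuple(bounds) if bounds is not None else None,
        integer=bool(entry.get("integer", False)),
    )


def load_catalogue(path) -> list:
    """Load a trait catalogue YAML into a list of :class:`TraitSpec`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    split = doc.get("variance_split", {"genetic": 0.5, "gxe": 0.1, "residual": 0.4})
    if abs(sum(split.values()) - 1.0) > 1e-9:
        raise CatalogueError(f"variance_split must sum to 1, got {split}")
    return [_spec_from_entry(entry, split) for entry in doc["traits"]]


def default_catalogue() -> list:
    """The built-in 24-trait drought-screen catalogue."""
    ref = resources.files("phenoscreen").joinpath("data/trait_catalogue.yaml")
    with resources.as_file(ref) as path:
        return load_catalogue(path)


@dataclass
class PhaseModel:
    """Piecewise fold-change trajectories of one genotype over a drought.

    ``trajectories`` maps trait -> {day: mean fold relative to the
    non-stressed control}; values between anchor days are linearly
    interpolated.  Day 0 is always fold 1.  ``phases`` records the day
    ranges of the three drought phases (early, induction, severe).
    """

    genotype: str
    tolerance_class: str  # "tolerant" or "susceptible"
    trajectories: dict
    phases: dict = field(
        default_factory=lambda: {"I": (1, 2), "II": (3, 8), "III": (9, 14)}
    )

    def mean_fold(self, trait: str, day: float) -> float:
        anchors = dict(self.trajectories[trait])
        anchors.setdefault(0, 1.0)
        days = np.array(sorted(anchors))
        return float(np.interp(day, days, [anchors[d] for d in days]))


def default_timecourse_models() -> dict:
    """Contrasting tolerant / susceptible 14-day trajectory defaults.

    The tolerant genotype proliferates peroxisomes early (phase II) and
    keeps water status and roots stable through severe stress; the
    susceptible one surges late (phase III) while relative water
    content, stomatal conductance and root growth collapse.
    """
    tolerant = PhaseModel(
        genotype="Onas",
        tolerance_class="tolerant",
        trajectories={
            "soil_moisture": {2: 0.9, 4: 0.7, 8: 0.25, 11: 0.1, 14: 0.05},
            "peroxisome_abundance": {2: 1.0, 4: 2.0, 6: 1.3, 8: 1.2, 11: 1.1, 14: 1.0},
            "relative_water_content": {8: 1.0, 11: 0.95, 14: 0.9},
            "stomatal_conductance": {2: 0.8, 8: 1.2, 11: 0.9, 14: 0.8},
            "root_length": {14: 1.0},
            "ros_content": {8: 1.0, 11: 1.5, 14: 2.0},
        },
    )
    susceptible = PhaseModel(
        genotype="Alpowa",
        tolerance_class="susceptible",
        trajectories={
            "soil_moisture": {2: 0.9, 4: 0.7, 8: 0.25, 11: 0.1, 14: 0.05},
            "peroxisome_abundance": {3: 1.0, 5: 1.5, 6: 1.0, 8: 1.0, 11: 2.5, 14: 3.5},
            "relative_water_content": {8: 0.8, 11: 0.5, 14: 0.3},
            "stomatal_conductance": {5: 0.9, 8: 0.4, 11: 0.2, 14: 0.1},
            "root_length": {8: 0.9, 11: 0.7, 14: 0.5},
            "ros_content": {5: 1.0, 8: 0.6, 11: 2.0, 14: 3.0},
        },
    )
    return {"tolerant": tolerant, "susceptible": susceptible}


def simulate_timecourse(
    model: PhaseModel,
    reps: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    days: list | None = None,
) -> PhenotypeTable:
    """Fold-change time course with multiplicative lognormal noise.

    Each observation is  mean_fold(trait, day) * exp(N(0, noise_sd^2)).
    Day 0 (fold 1) is included so baselines are explicit.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if days is None:
        days = list(range(0, 15))
    rows = []
    for trait in sorted(model.trajectories):
        for day in days:
            mean = model.mean_fold(trait, day)
            noise = np.exp(noise_sd * rng.standard_normal(reps)) if noise_sd else np.ones(reps)
            for rep in range(1, reps + 1):
                rows.append(
                    {
                        "genotype": model.genotype,
                        "environment": STRESSED,
                        "replicate": rep,
                        "trait": trait,
                        "value": mean * noise[rep - 1],
                        "day": day,
                    }
                )
    return phenotype_table_from_frame(pd.DataFrame(rows))


def default_gene_folds() -> pd.DataFrame:
    """Default true expression folds of the peroxisome-biogenesis panel.

    Two contrasting genotypes x three sampling days (3, 8, 14) covering
    the drought phases: a few early inductions specific to each genotype,
    then a general up-regulation at day 14 that is stronger in the
    tolerant genotype.  Stressed cells only; non-stressed calibrator
    cells (fold 1) are added by :func:`simulate_qpcr`.
    """
    folds = {
        ("Onas", 3): {"TaDRP3A": 1.2, "TaDRP3B": 1.6},
        ("Alpowa", 3): {"TaDRP5B": 1.9},
        ("Onas", 8): {"TaFIS1A": 2.0},
        ("Alpowa", 8): {"TaPEX11-5": 1.8, "TaDRP5B": 1.6},
        ("Onas", 14): {
            "TaPEX11-3": 3.0, "TaPEX11-4": 2.8, "TaPEX11-5": 3.5,
            "TaFIS1A": 3.2, "TaDRP3A": 2.0, "TaDRP3B": 2.2, "TaDRP5B": 3.0,
        },
        ("Alpowa", 14): {
            "TaPEX11-3": 2.0, "TaPEX11-4": 1.8, "TaPEX11-5": 2.2,
            "TaFIS1A": 1.5, "TaDRP3A": 1.6, "TaDRP3B": 1.8, "TaDRP5B": 1.9,
        },
    }
    rows = [
        {
            "genotype": genotype,
            "treatment": STRESSED,
            "day": day,
            "gene": gene,
            "fold": cell.get(gene, 1.0),
        }
        for (genotype, day), cell in folds.items()
        for gene in PEROXISOME_GENES
    ]
    return pd.DataFrame(rows)


def simulate_qpcr(
    true_folds: pd.DataFrame,
    ct_base: float = 25.0,
    sd_tech: float = 0.0,
    sd_bio: float = 0.0,
    seed: int = 0,
    n_bio: int = 3,
    n_tech: int = 3,
    housekeeping: str = "actin",
    hk_offset: float = 0.0,
) -> pd.DataFrame:
    """Generate a raw Ct table whose true expression folds are known.

    ``true_folds`` has columns genotype, treatment, day, gene, fold.  For
    every (genotype, day, gene) lacking a non-stressed row, a calibrator
    row with fold 1 is added.  The generative model is the comparative-Ct
    one:  Ct_target = ct_base - log2(fold) + bio + tech  with Gaussian
    biological and technical noise; the housekeeping gene sits flat at
    ``ct_base + hk_offset`` plus its own noise.
    """
    folds = true_folds.copy()
    if (folds["fold"] <= 0).any():
        raise ParameterError("true folds must be positive")
    have = set(zip(folds["genotype"], folds["day"], folds["gene"]))
    cal_rows = [
        {"genotype": g, "treatment": NON_STRESSED, "day": d, "gene": gene, "fold": 1.0}
        for (g, d, gene) in sorted(have)
        if not (
            (folds["genotype"] == g)
            & (folds["day"] == d)
            & (folds["gene"] == gene)
            & (folds["treatment"] == NON_STRESSED)
        ).any()
    ]
    if cal_rows:
        folds = pd.concat([folds, pd.DataFrame(cal_rows)], ignore_index=True)

    rng = np.random.default_rng(seed)
    records = []
    for _, row in folds.iterrows():
        for bio in range(1, n_bio + 1):
            bio_t = sd_bio * rng.standard_normal() if sd_bio else 0.0
            for tech in range(1, n_tech + 1):
                tech_t = sd_tech * rng.standard_normal() if sd_tech else 0.0
                records.append(
                    {
                        "genotype": row["genotype"],
                        "treatment": row["treatment"],
                        "day": row["day"],
                        "gene": row["gene"],
                        "biological_rep": bio,
                        "technical_rep": tech,
                        "ct": ct_base - np.log2(row["fold"]) + bio_t + tech_t,
                    }
                )
    # One housekeeping measurement set per sample (genotype/treatment/day/bio).
    samples = folds[["genotype", "treatment", "day"]].drop_duplicates()
    for _, row in samples.iterrows():
        for bio in range(1, n_bio + 1):
            bio_h = sd_bio * rng.standard_normal() if sd_bio else 0.0
            for tech in range(1, n_tech + 1):
                tech_h = sd_tech * rng.standard_normal() if sd_tech else 0.0
                records.append(
                    {
                        "genotype": row["genotype"],
                        "treatment": row["treatment"],
                        "day": row["day"],
                        "gene": housekeeping,
                        "biological_rep": bio,
                        "technical_rep": tech,
                        "ct": ct_base + hk_offset + bio_h + tech_h,
                    }
                )
    return qpcr_table_from_frame(pd.DataFrame(records))
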