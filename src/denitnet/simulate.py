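"""Seeded synthetic-data generator emulating the field-study design.

Everything downstream of sequencing and gas chromatography is generated
with known ground truth: treatment-structured soil covariates drawn from
the built-in per-treatment table, three functional-gene OTU tables with
planted co-abundance modules and keystone OTUs, and noisy chamber closure
series generated from known fluxes.

Count model: each OTU has a log-scale latent abundance

    z_ij = mu_i + s * signal_ij

where mu_i is a per-OTU baseline (log-normal abundance distribution) and
signal_ij is a unit-variance factor construction. Regular members of a
module load sqrt(rho) on the module factor (the standardized driver trait,
or an independent latent factor), so their pairwise latent correlation is
rho. Keystone OTUs load on an equal mix of the module factor and the pooled
idiosyncratic noise of half the regular members, which raises their
correlation with those members above the regular-pair level — elevated
connectivity by construction. Columns are closed by a softmax and counts
drawn multinomially to a fixed depth, the compositional noise model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import flux as fluxmod
from .datasets import GENUS_POOLS, TRAITS, soil_property_table
from .design import StudyDesign
from .io import OtuTable


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ModulePlan:
    """One planted co-abundance module.

    driver_trait: soil covariate whose standardized per-sample values act as
    the module's latent factor (None = independent latent factor);
    driver_sign: +1/-1 orientation of the module on that trait;
    within_module_correlation: target pairwise latent correlation among
    regular members, in (0, 1]; n_keystones members are planted with
    elevated connectivity at ``keystone_strength``.
    """

    module_id: str
    n_otus: int
    driver_trait: str | None = None
    driver_sign: int = 1
    within_module_correlation: float = 0.85
    n_keystones: int = 0
    keystone_strength: float = 0.95
    keystone_link_fraction: float = 1.0   # fraction (>= 0.5) of members tracked

    def __post_init__(self) -> None:
        if self.n_otus < 1:
            raise ConfigurationError(f"module {self.module_id}: n_otus must be positive")
        if not (0.0 < self.within_module_correlation <= 1.0):
            raise ConfigurationError(
                f"module {self.module_id}: within_module_correlation must be in (0, 1], "
                f"got {self.within_module_correlation} (not attainable)")
        if self.driver_sign not in (-1, 1):
            raise ConfigurationError(f"module {self.module_id}: driver_sign must be +1/-1")
        if not (0 <= self.n_keystones < self.n_otus):
            raise ConfigurationError(
                f"module {self.module_id}: keystones must be a strict subset of members")
        if not (0.0 < self.keystone_strength <= 1.0):
            raise ConfigurationError(f"module {self.module_id}: keystone_strength in (0, 1]")
        if not (0.5 <= self.keystone_link_fraction <= 1.0):
            raise ConfigurationError(
                f"module {self.module_id}: keystones must link to at least half "
                "of the module members (keystone_link_fraction in [0.5, 1])")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring downstream."""

    otu_module: dict[str, str] = field(default_factory=dict)   # otu -> module or "background"
    keystones: list[str] = field(default_factory=list)
    trait_correlation_signs: dict[str, dict[str, int]] = field(default_factory=dict)
    true_fluxes: dict = field(default_factory=dict)            # plot -> {day: ug m-2 h-1}


# physically valid ranges used to truncate covariate draws
_BOUNDS = {"pH": (1e-9, 14.0), "SWC": (0.0, 100.0)}
_DEFAULT_BOUNDS = (0.0, np.inf)


def generate_soil_covariates(design: StudyDesign,
                             trait_means_sds: pd.DataFrame | None = None,
                             seed: int | None = None) -> pd.DataFrame:
    """Per-sample soil covariates ~ truncated Normal(treatment mean, SD).

    ``trait_means_sds`` is a long frame (trait, treatment, mean, sd);
    defaults to the built-in per-treatment table (which includes the
    synthetic PDA and cumulative-N2O response rows). A missing
    trait/treatment combination is a configuration error.
    """
    if trait_means_sds is None:
        trait_means_sds = soil_property_table()
    if (trait_means_sds["sd"] < 0).any():
        bad = trait_means_sds.loc[trait_means_sds["sd"] < 0].iloc[0]
        raise ConfigurationError(f"negative SD for {bad['trait']}/{bad['treatment']}")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    lookup = trait_means_sds.set_index(["trait", "treatment"])
    traits = list(dict.fromkeys(trait_means_sds["trait"]))
    rows = []
    for treatment in design.treatments:
        for rep in range(1, design.replicates + 1):
            row = {"sample_id": f"{treatment}-{rep}", "treatment": treatment,
                   "replicate": rep}
            for trait in traits:
                try:
                    mean, sd = lookup.loc[(trait, treatment), ["mean", "sd"]]
                except KeyError:
                    raise ConfigurationError(
                        f"no mean/SD configured for trait {trait!r}, "
                        f"treatment {treatment!r}") from None
                lo, hi = _BOUNDS.get(trait, _DEFAULT_BOUNDS)
                if sd == 0:
                    row[trait] = float(mean)
                else:
                    a, b = (lo - mean) / sd, (hi - mean) / sd
                    row[trait] = float(truncnorm.rvs(a, b, loc=mean, scale=sd,
                                                     random_state=rng))
            rows.append(row)
    return pd.DataFrame(rows)


def _module_signals(plan: ModulePlan, factor: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-variance latent signals, rows = module members (keystones last)."""
    n = factor.size
    rho, a = plan.within_module_correlation, math.sqrt(plan.within_module_correlation)
    n_reg = plan.n_otus - plan.n_keystones
    eps = rng.standard_normal((plan.n_otus, n))
    signals = np.empty((plan.n_otus, n))
    signals[:n_reg] = a * factor + math.sqrt(1.0 - rho) * eps[:n_reg]
    if plan.n_keystones:
        # keystone latent profile tracks the mean profile of a fraction
        # (>= 1/2) of the regular members, so its correlation with them,
        # ~ sqrt(rho + (1-rho)/n_link), exceeds the regular pairwise level rho
        n_link = max(1, math.ceil(plan.keystone_link_fraction * n_reg))
        hub = signals[:n_link].mean(axis=0) / math.sqrt(rho + (1.0 - rho) / n_link)
        ak = plan.keystone_strength
        signals[n_reg:] = ak * hub + math.sqrt(1.0 - ak**2) * eps[n_reg:]
    return signals


def generate_otu_table(design: StudyDesign, modules: list[ModulePlan],
                       n_background_otus: int = 0, depth: int = 10_000,
                       seed: int = 0, frame: pd.DataFrame | None = None,
                       gene_tag: str = "nirS", genus_pool=None,
                       log_sd: float = 0.5, abundance_spread: float = 1.0
                       ) -> tuple[OtuTable, GroundTruth]:
    """Seeded OTU count table with planted modules and keystones.

    ``frame`` supplies the soil covariates whose standardized values drive
    trait-linked modules (generated from the built-in table when omitted).
    ``depth`` is the fixed per-sample sequencing depth (column sum);
    ``log_sd`` scales biological (log-space) variation relative to the
    per-OTU baseline spread ``abundance_spread``.
    """
    if depth <= 0:
        raise ConfigurationError("depth must be positive")
    ids = [p.module_id for p in modules]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("module ids must be unique")
    rng = np.random.default_rng(seed)
    if frame is None:
        frame = generate_soil_covariates(design, seed=rng.integers(0, 2**31 - 1))
    frame = frame.set_index("sample_id").loc[design.sample_ids()].reset_index()
    n_samples = design.n_samples
    genus_pool = tuple(genus_pool) if genus_pool is not None \
        else GENUS_POOLS.get(gene_tag, GENUS_POOLS["nirS"])

    signal_rows, truth = [], GroundTruth()
    otu_counter = 0

    def new_ids(k: int) -> list[str]:
        nonlocal otu_counter
        out = [f"{gene_tag}_OTU{otu_counter + i:04d}" for i in range(k)]
        otu_counter += k
        return out

    all_ids: list[str] = []
    for plan in modules:
        if plan.driver_trait is not None:
            if plan.driver_trait not in frame.columns:
                raise ConfigurationError(
                    f"module {plan.module_id}: driver trait {plan.driver_trait!r} "
                    "missing from the sample frame")
            vals = frame[plan.driver_trait].to_numpy(dtype=float)
            factor = plan.driver_sign * (vals - vals.mean()) / vals.std()
            truth.trait_correlation_signs[plan.module_id] = {
                plan.driver_trait: plan.driver_sign}
        else:
            factor = rng.standard_normal(n_samples)
        signal_rows.append(_module_signals(plan, factor, rng))
        member_ids = new_ids(plan.n_otus)
        all_ids.extend(member_ids)
        for oid in member_ids:
            truth.otu_module[oid] = plan.module_id
        n_reg = plan.n_otus - plan.n_keystones
        truth.keystones.extend(member_ids[n_reg:])
    if n_background_otus:
        signal_rows.append(rng.standard_normal((n_background_otus, n_samples)))
        bg_ids = new_ids(n_background_otus)
        all_ids.extend(bg_ids)
        for oid in bg_ids:
            truth.otu_module[oid] = "background"

    signals = np.vstack(signal_rows) if signal_rows else np.empty((0, n_samples))
    n_otus = signals.shape[0]
    if n_otus == 0:
        raise ConfigurationError("no OTUs configured")
    mu = rng.normal(0.0, abundance_spread, size=n_otus)
    z = mu[:, None] + log_sd * signals
    p = np.exp(z - z.max(axis=0))
    p /= p.sum(axis=0)
    counts = np.column_stack([rng.multinomial(depth, p[:, j]) for j in range(n_samples)])
    genus = pd.Series(rng.choice(genus_pool, size=n_otus), index=all_ids, name="genus")
    table = OtuTable(pd.DataFrame(counts, index=all_ids, columns=design.sample_ids()),
                     genus, gene_tag)
    return table, truth


def generate_chamber_series(true_flux: float,
                            volume_m3: float = fluxmod.DEFAULT_CHAMBER_VOLUME,
                            area_m2: float = fluxmod.DEFAULT_CHAMBER_AREA,
                            temperature_c: float = 20.0,
                            sampling_times=(0.0, 10.0, 20.0),
                            noise_sd: float = 0.0,
                            baseline_conc: float = 0.33,
                            gas_density: float = fluxmod.N2O_DENSITY_STP,
                            seed: int = 0, plot_id: str | None = None,
                            date_day: float | None = None) -> fluxmod.ChamberSeries:
    """A chamber closure series whose linear trend encodes ``true_flux``.

    Inverts the chamber flux equation for the concentration slope, builds a
    linear accumulation from an ambient ``baseline_conc`` (ul l-1) and adds
    Gaussian noise; ``true_flux`` is in ug m-2 h-1.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    times = np.asarray(sampling_times, dtype=float)
    slope = true_flux / (gas_density * (volume_m3 / area_m2)
                         * 273.0 / (273.0 + temperature_c))   # ul l-1 h-1
    conc = baseline_conc + slope * times / 60.0
    if noise_sd > 0:
        conc = conc + np.random.default_rng(seed).normal(0.0, noise_sd, size=times.size)
    return fluxmod.ChamberSeries(times, conc, volume_m3, area_m2, temperature_c,
                                 gas_density, plot_id=plot_id, date_day=date_day)


# ---------------------------------------------------------------------------
# Whole-study assembly

def default_module_plans(gene_tag: str) -> list[ModulePlan]:
    """Study-like module plans: per gene, four modules echoing the reported
    qualitative structure (module I trait-linked to nitrate, keystones in
    module I), with mutually weakly-correlated drivers."""
    sign_no3 = {"nirK": 1, "nirS": 1, "nosZ": -1}[gene_tag]
    return [
        ModulePlan("I", 10, "NO3_N", sign_no3, 0.85, n_keystones=2),
        ModulePlan("II", 8, "SOC", 1, 0.85),
        ModulePlan("III", 6, "DON", 1, 0.85),
        ModulePlan("IV", 6, None, 1, 0.85),
    ]


def seasonal_flux_profile(days=None, peak_day: float = 60.0,
                          peak_width: float = 25.0, base_mg: float = 0.01,
                          peak_mg: float = 0.0494) -> pd.Series:
    """Season-shaped reference flux curve in mg m-2 h-1 (mid-summer peak),
    sampled at 15-day chamber dates by default; scaled per treatment by the
    cumulative-emission ratios of the built-in table."""
    if days is None:
        days = np.arange(0.0, 136.0, 15.0)
    days = np.asarray(days, dtype=float)
    f = base_mg + peak_mg * np.exp(-(((days - peak_day) / peak_width) ** 2))
    return pd.Series(f, index=days)


@dataclass
class SimulatedStudy:
    design: StudyDesign
    frame: pd.DataFrame
    tables: dict[str, tuple[OtuTable, GroundTruth]]
    chambers: list
    true_fluxes: pd.DataFrame    # plot_id, treatment, date_day, flux_ug_m2_h


def simulate_study(seed: int = 0, design: StudyDesign | None = None,
                   depth: int = 10_000, n_background_otus: int = 20,
                   chamber_noise_sd: float = 0.003,
                   module_plans: dict[str, list[ModulePlan]] | None = None
                   ) -> SimulatedStudy:
    """Generate the full input surface of the emulated study.

    One seeded call yields the soil/metadata frame (15 samples by default),
    three OTU tables with ground truth, and per-plot chamber closure series
    across ten 15-day sampling dates whose underlying fluxes scale with each
    treatment's cumulative-N2O ratio.
    """
    design = design or StudyDesign(seed=seed)
    rng = np.random.default_rng(seed)
    frame = generate_soil_covariates(design, seed=int(rng.integers(0, 2**31 - 1)))
    tables = {}
    for gene in ("nirK", "nirS", "nosZ"):
        plans = (module_plans or {}).get(gene, default_module_plans(gene))
        tables[gene] = generate_otu_table(
            design, plans, n_background_otus=n_background_otus, depth=depth,
            seed=int(rng.integers(0, 2**31 - 1)), frame=frame, gene_tag=gene)

    profile = seasonal_flux_profile()
    ratios = soil_property_table().query("trait == 'N2O'").set_index("treatment")["mean"]
    ratios = ratios / ratios["CK"]
    chambers, flux_rows = [], []
    for plot in design.sample_ids():
        treatment = design.treatment_of()[plot]
        for day, f_mg in profile.items():
            f_ug = 1000.0 * f_mg * float(ratios[treatment])
            chambers.append(generate_chamber_series(
                f_ug, noise_sd=chamber_noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)), plot_id=plot, date_day=day))
            flux_rows.append((plot, treatment, day, f_ug))
    true_fluxes = pd.DataFrame(flux_rows, columns=["plot_id", "treatment",
                                                   "date_day", "flux_ug_m2_h"])
    return SimulatedStudy(design, frame, tables, chambers, true_fluxes)
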