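"""Synthetic GC-EI-MS corpus generator.

Emulates the statistical structure a unit-mass EI library exhibits:
scaffold-specific fragmentation signatures (molecular ion, sequential
substituent losses, fixed characteristic fragments), homolog ladders whose
spectra are pattern-similar but mass-shifted, Kovats-like retention indices
that grow with molecular size, ClassyFire-style taxonomy labels, and
physicochemical/toxicity properties drawn from known linear structure →
property models with Gaussian noise.  Because the generating models are
known, downstream QSAR recovery is testable against ground truth.

The default scaffold set spans the regimes the analysis cares about:

* ``pcb_like`` — aromatic chlorination ladder (biphenyl + k Cl, +34 u per
  substitution); adjacent homologs share fixed fragments (77, 152 u) but the
  molecular-ion/loss ladder shifts, so binned spectra diverge while
  structure fingerprints stay similar.
* ``alkane_like`` — aliphatic CH2 ladder with the classic 43/57/71 series.
* ``alkylbenzene`` — monosubstituted benzenoid with tropylium-style 91/77/65
  fragments.
* ``methyl_ester`` — oxygenated aliphatic with 74/59/43-style ions.

Boiling point and retention index additionally share a per-compound latent
"shape" factor: molecules that elute late for their mass also boil high.
This keeps measured RI genuinely informative for BP beyond what the spectrum
alone encodes, as it is for real isomer sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .spectra_io import ColumnPolarity, Dataset, SpectrumRecord

__all__ = [
    "ScaffoldSpec",
    "RIModel",
    "PropertyModel",
    "GeneratorConfig",
    "default_scaffolds",
    "default_config",
    "generate_dataset",
    "generate_homolog_ladder",
    "spectrum_from_structure",
    "property_from_structure",
]


@dataclass(frozen=True)
class ScaffoldSpec:
    """A fragmentation archetype plus the SMILES builder for its homologs."""

    name: str
    smiles_template: str  # human-readable; {k} marks the substitution count
    smiles_builder: Callable[[int], str]
    base_nominal_mass: int  # u, at substituent_count = 0
    mass_per_substituent: int  # u added per substitution step
    #: (mass, weight, k_drift): effective weight = weight * exp(k_drift * k),
    #: so the relative pattern of the shared fragment bins rotates gradually
    #: along a homolog ladder, as it does in real EI series
    characteristic_fragments: tuple[tuple[int, float, float], ...]
    neutral_losses: tuple[int, ...]  # sequential; last entry repeats
    superclass_label: str
    class_label: str
    aromatic: bool
    #: (base_mass, weight, decay): a homolog-shared fragment family at
    #: base_mass + mass_per_substituent * j for j < k, weighted
    #: weight * decay**(k-1-j).  Emulates the series real EI spectra share
    #: along a ladder (dechlorinated core ions for PCBs, C_nH_{2n+1}+ for
    #: alkanes, acylium/benzylic series for esters/alkylbenzenes), which
    #: makes homolog similarity decay gradually with the substitution gap.
    core_series: tuple[int, float, float] | None = None
    #: cap on the number of sequential-loss peaks (None = one per substituent);
    #: scaffolds whose deep fragmentation collapses onto the core series keep
    #: only the first loss(es) as distinct ions
    max_losses: int | None = None
    #: inclusive substituent-count range typical for the family (overrides the
    #: config-level distribution), e.g. C5-C25 for n-alkanes
    substituent_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if any(m >= self.base_nominal_mass for m, *_ in self.characteristic_fragments):
            raise ValueError(
                f"scaffold {self.name!r}: characteristic fragment >= base mass"
            )
        if any(loss <= 0 for loss in self.neutral_losses):
            raise ValueError(f"scaffold {self.name!r}: non-positive neutral loss")

    def nominal_mass(self, substituent_count: int) -> int:
        return self.base_nominal_mass + self.mass_per_substituent * substituent_count


def _pcb_smiles(k: int) -> str:
    """Biphenyl with k chlorines on fixed ring positions (k <= 10).

    Chlorines alternate between the rings (ring A gets the extra one for odd
    k), which keeps adjacent congeners' atom environments similar the way
    real congener series are; each ring is written starting at the ring-ring
    bond carbon.
    """
    if not 0 <= k <= 10:
        raise ValueError("PCB-like scaffold supports 0-10 chlorines")
    m1, m2 = (k + 1) // 2, k // 2

    def ring(m: int, label: int) -> str:
        body = "".join("c(Cl)" if i < min(m, 4) else "c" for i in range(4))
        tail = f"c{label}Cl" if m == 5 else f"c{label}"
        return f"c{label}{body}{tail}"

    return f"c1(-{ring(m2, 2)}){ring(m1, 1)[2:]}"


def _alkane_smiles(k: int) -> str:
    return "C" * (5 + k)


def _alkylbenzene_smiles(k: int) -> str:
    return "C" * (k + 1) + "c1ccccc1"


def _methyl_ester_smiles(k: int) -> str:
    return "COC(=O)" + "C" * (k + 1)


def default_scaffolds() -> dict[str, ScaffoldSpec]:
    return {
        "pcb_like": ScaffoldSpec(
            name="pcb_like",
            smiles_template="biphenyl + {k} Cl",
            smiles_builder=_pcb_smiles,
            base_nominal_mass=154,  # C12H10
            mass_per_substituent=34,  # +Cl(35) -H(1)
            characteristic_fragments=(
                (51, 0.10, -0.04),
                (75, 0.15, -0.04),
                (77, 0.30, -0.06),
            ),
            neutral_losses=(35,),  # a single distinct [M-Cl]+ ion
            max_losses=1,  # deeper dechlorination collapses onto the core grid
            core_series=(152, 0.40, 0.78),  # dechlorinated biphenylene ions
            substituent_range=(0, 10),
            superclass_label="Benzenoids",
            class_label="Polychlorinated biphenyls",
            aromatic=True,
        ),
        "alkane_like": ScaffoldSpec(
            name="alkane_like",
            smiles_template="n-alkane C{5+k}",
            smiles_builder=_alkane_smiles,
            base_nominal_mass=72,  # C5H12
            mass_per_substituent=14,
            characteristic_fragments=((43, 0.60, -0.05), (57, 0.55, 0.0), (71, 0.40, 0.01)),
            neutral_losses=(15, 14),  # CH3 then CH2 ladder
            core_series=(85, 0.35, 0.80),  # CnH2n+1+ series beyond C5
            substituent_range=(0, 20),  # C5-C25
            superclass_label="Lipids and lipid-like molecules",
            class_label="Alkanes",
            aromatic=False,
        ),
        "alkylbenzene": ScaffoldSpec(
            name="alkylbenzene",
            smiles_template="C6H5-(CH2){k}-CH3",
            smiles_builder=_alkylbenzene_smiles,
            base_nominal_mass=92,  # toluene
            mass_per_substituent=14,
            characteristic_fragments=((91, 0.55, 0.0), (77, 0.35, -0.04), (65, 0.18, -0.02)),
            neutral_losses=(15, 14),
            core_series=(105, 0.30, 0.80),  # methyltropylium-type series
            substituent_range=(0, 16),
            superclass_label="Benzenoids",
            class_label="Alkylbenzenes",
            aromatic=True,
        ),
        "methyl_ester": ScaffoldSpec(
            name="methyl_ester",
            smiles_template="CH3-O-CO-(CH2){k}-CH3",
            smiles_builder=_methyl_ester_smiles,
            base_nominal_mass=74,  # methyl acetate
            mass_per_substituent=14,
            characteristic_fragments=((43, 0.40, -0.04), (59, 0.50, 0.0), (71, 0.25, 0.0)),
            neutral_losses=(31, 14),  # OCH3 then CH2 ladder
            core_series=(87, 0.30, 0.80),  # acylium-type series
            substituent_range=(0, 18),
            superclass_label="Organic oxygen compounds",
            class_label="Fatty acid methyl esters",
            aromatic=False,
        ),
    }


@dataclass(frozen=True)
class RIModel:
    """Kovats-like retention index: intercept + slope·mass (+ offset if aromatic).

    ``latent_scale`` couples a per-compound standard-normal shape factor into
    the RI; the same factor enters BP (see :class:`GeneratorConfig`).
    """

    intercept: float = 0.0
    per_mass_slope: float = 7.0  # alkane ladder: RI 100 per CH2 = 14 u
    polarity_offset: float = 120.0  # aromatic retention on a semi-polar column
    noise_sd: float = 10.0
    latent_scale: float = 15.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PropertyModel:
    """Linear model on (nominal mass, substituent count, aromatic flag)."""

    intercept: float
    mass_coef: float
    substituent_coef: float
    aromatic_coef: float
    noise_sd: float
    latent_scale: float = 0.0  # coupling to the shared RI/BP shape factor

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def mean(self, mass: int, substituent_count: int, aromatic: bool) -> float:
        return (
            self.intercept
            + self.mass_coef * mass
            + self.substituent_coef * substituent_count
            + self.aromatic_coef * float(aromatic)
        )


def default_property_models() -> dict[str, PropertyModel]:
    # magnitudes chosen to put each property in its real-world range over
    # the generated mass span (~70-500 u)
    return {
        "bp": PropertyModel(30.0, 1.05, 8.0, 20.0, noise_sd=8.0, latent_scale=8.0),
        "mp": PropertyModel(-90.0, 0.70, 18.0, 40.0, noise_sd=18.0),
        "log_kow": PropertyModel(0.5, 0.012, 0.80, 0.30, noise_sd=0.35),
        "log_ws": PropertyModel(2.5, -0.015, -0.80, -0.50, noise_sd=0.50),
        "log_ld50_rat_oral": PropertyModel(3.6, -0.003, -0.30, -0.40, noise_sd=0.45),
        "log_ld50_mouse_oral": PropertyModel(3.4, -0.0025, -0.25, -0.35, noise_sd=0.45),
    }


@dataclass
class GeneratorConfig:
    n_compounds: int = 1000
    scaffold_mix: dict[str, float] = field(
        default_factory=lambda: {
            "pcb_like": 0.25,
            "alkane_like": 0.25,
            "alkylbenzene": 0.25,
            "methyl_ester": 0.25,
        }
    )
    substituent_count_distribution: dict[int, float] = field(
        default_factory=lambda: {k: 1.0 / 9.0 for k in range(9)}
    )
    ri_model: RIModel = field(default_factory=RIModel)
    property_models: dict[str, PropertyModel] = field(
        default_factory=default_property_models
    )
    intensity_noise_cv: float = 0.10
    #: mean count of small incidental fragment peaks per spectrum (Poisson);
    #: real EI spectra carry many minor ions, so bin counts are noisy
    minor_peak_rate: float = 6.0
    seed: int = 1
    scaffolds: dict[str, ScaffoldSpec] = field(default_factory=default_scaffolds)

    def __post_init__(self) -> None:
        if self.n_compounds <= 0:
            raise ValueError("n_compounds must be positive")
        if not self.scaffold_mix:
            raise ValueError("scaffold_mix is empty")
        total = sum(self.scaffold_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scaffold_mix sums to {total}, expected 1")
        unknown = set(self.scaffold_mix) - set(self.scaffolds)
        if unknown:
            raise ValueError(f"scaffold_mix references unknown scaffolds {unknown}")
        if self.intensity_noise_cv < 0:
            raise ValueError("intensity_noise_cv must be >= 0")


def default_config(**overrides) -> GeneratorConfig:
    return GeneratorConfig(**overrides)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def spectrum_from_structure(
    scaffold: ScaffoldSpec,
    substituent_count: int,
    rng: np.random.Generator,
    intensity_noise_cv: float = 0.10,
    minor_peak_rate: float = 6.0,
) -> list[tuple[float, float]]:
    """EI peak list: molecular ion, losses, fragment series, minor ions.

    Intensities carry multiplicative log-normal noise with the given CV and
    are rescaled so the base peak is 999.  The molecular ion has the largest
    deterministic weight, so it is (up to noise) the base peak.  A
    Poisson(``minor_peak_rate``) number of weak incidental peaks at random
    masses below the molecular ion emulates the minor-ion background of
    real EI spectra.
    """
    if substituent_count < 0:
        raise ValueError("substituent_count must be >= 0")
    mol_ion = scaffold.nominal_mass(substituent_count)
    weights: dict[int, float] = {mol_ion: 1.0}
    mass = mol_ion
    n_losses = substituent_count
    if scaffold.max_losses is not None:
        n_losses = min(n_losses, scaffold.max_losses)
    for i in range(n_losses):
        mass -= scaffold.neutral_losses[min(i, len(scaffold.neutral_losses) - 1)]
        if mass <= 0:
            break
        weights[mass] = weights.get(mass, 0.0) + 0.55 * (0.80**i)
    if scaffold.core_series is not None:
        base, weight, decay = scaffold.core_series
        for j in range(substituent_count):
            m = base + scaffold.mass_per_substituent * j
            if m >= mol_ion:
                break
            eff = weight * decay ** (substituent_count - 1 - j)
            weights[m] = weights.get(m, 0.0) + eff
    for frag_mass, weight, k_drift in scaffold.characteristic_fragments:
        eff = weight * math.exp(k_drift * substituent_count)
        weights[frag_mass] = weights.get(frag_mass, 0.0) + eff

    if minor_peak_rate > 0:
        n_minor = int(rng.poisson(minor_peak_rate))
        lo = 35
        if mol_ion - 1 > lo:
            for m in rng.integers(lo, mol_ion, size=n_minor):
                w = float(rng.uniform(0.005, 0.04))
                weights[int(m)] = weights.get(int(m), 0.0) + w
    masses = np.array(sorted(weights), dtype=float)
    inten = np.array([weights[int(m)] for m in masses])
    if intensity_noise_cv > 0:
        sigma = math.sqrt(math.log1p(intensity_noise_cv**2))
        inten = inten * rng.lognormal(-0.5 * sigma**2, sigma, size=inten.shape)
    inten = inten * (999.0 / inten.max())
    return list(zip(masses.tolist(), inten.tolist()))


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


def property_from_structure(
    scaffold: ScaffoldSpec,
    substituent_count: int,
    property_models: Mapping[str, PropertyModel],
    rng: np.random.Generator,
    latent: float | None = None,
) -> dict[str, float]:
    """Property map: exact log10 molecular mass plus noisy linear models."""
    mass = scaffold.nominal_mass(substituent_count)
    if latent is None:
        latent = float(rng.standard_normal())
    props = {"log_mw": math.log10(mass)}
    for name, model in property_models.items():
        value = model.mean(mass, substituent_count, scaffold.aromatic)
        value += model.latent_scale * latent
        if model.noise_sd > 0:
            value += float(rng.normal(0.0, model.noise_sd))
        props[name] = value
    return props


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def generate_dataset(config: GeneratorConfig | None = None) -> Dataset:
    """Deterministically generate a full synthetic library from ``config``."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    scaffold_names = sorted(config.scaffold_mix)
    scaffold_probs = np.array([config.scaffold_mix[n] for n in scaffold_names])
    sub_counts = sorted(config.substituent_count_distribution)
    sub_probs = np.array(
        [config.substituent_count_distribution[k] for k in sub_counts], dtype=float
    )
    sub_probs = sub_probs / sub_probs.sum()

    records: list[SpectrumRecord] = []
    width = len(str(config.n_compounds))
    for i in range(config.n_compounds):
        scaffold = config.scaffolds[
            scaffold_names[int(rng.choice(len(scaffold_names), p=scaffold_probs))]
        ]
        if scaffold.substituent_range is not None:
            k_lo, k_hi = scaffold.substituent_range
            k = int(rng.integers(k_lo, k_hi + 1))
        else:
            k = int(np.asarray(sub_counts)[int(rng.choice(len(sub_counts), p=sub_probs))])
        latent = float(rng.standard_normal())
        peaks = spectrum_from_structure(
            scaffold,
            k,
            rng,
            intensity_noise_cv=config.intensity_noise_cv,
            minor_peak_rate=config.minor_peak_rate,
        )
        mass = scaffold.nominal_mass(k)
        rim = config.ri_model
        ri = (
            rim.intercept
            + rim.per_mass_slope * mass
            + (rim.polarity_offset if scaffold.aromatic else 0.0)
            + rim.latent_scale * latent
            + (float(rng.normal(0.0, rim.noise_sd)) if rim.noise_sd > 0 else 0.0)
        )
        props = property_from_structure(
            scaffold, k, config.property_models, rng, latent=latent
        )
        records.append(
            SpectrumRecord(
                compound_id=f"SYN-{i + 1:0{width}d}",
                name=f"{scaffold.name} k={k} #{i + 1}",
                smiles=scaffold.smiles_builder(k),
                ri=max(ri, 0.0),
                column_polarity=ColumnPolarity.semi_polar,
                peaks=peaks,
                class_labels={
                    "kingdom": "Organic compounds",
                    "superclass": scaffold.superclass_label,
                    "class": scaffold.class_label,
                },
                properties=props,
                metadata={"Scaffold": scaffold.name, "Substituents": str(k)},
            )
        )
    return Dataset(
        records=records,
        provenance=f"synthetic(seed={config.seed}, n={config.n_compounds})",
        global_mz_range=Dataset.infer_range(records),
    )


def generate_homolog_ladder(
    k_min: int = 1,
    k_max: int = 10,
    replicates: int = 5,
    intensity_noise_cv: float = 0.05,
    seed: int = 1,
    scaffold: ScaffoldSpec | None = None,
    config: GeneratorConfig | None = None,
) -> Dataset:
    """A chlorination-ladder library: ``replicates`` spectra per homolog.

    Each record's ``metadata['Substituents']`` stores the chlorine count so
    homolog-contrast analyses can recover it.
    """
    config = config or GeneratorConfig()
    scaffold = scaffold or config.scaffolds["pcb_like"]
    rng = np.random.default_rng(seed)
    records: list[SpectrumRecord] = []
    for k in range(k_min, k_max + 1):
        for rep in range(replicates):
            latent = float(rng.standard_normal())
            peaks = spectrum_from_structure(
                scaffold,
                k,
                rng,
                intensity_noise_cv=intensity_noise_cv,
                minor_peak_rate=config.minor_peak_rate,
            )
            mass = scaffold.nominal_mass(k)
            rim = config.ri_model
            ri = (
                rim.intercept
                + rim.per_mass_slope * mass
                + (rim.polarity_offset if scaffold.aromatic else 0.0)
                + rim.latent_scale * latent
                + float(rng.normal(0.0, rim.noise_sd))
            )
            records.append(
                SpectrumRecord(
                    compound_id=f"{scaffold.name}-k{k}-r{rep + 1}",
                    name=f"{scaffold.name} k={k} replicate {rep + 1}",
                    smiles=scaffold.smiles_builder(k),
                    ri=max(ri, 0.0),
                    column_polarity=ColumnPolarity.semi_polar,
                    peaks=peaks,
                    class_labels={
                        "kingdom": "Organic compounds",
                        "superclass": scaffold.superclass_label,
                        "class": scaffold.class_label,
                    },
                    properties=property_from_structure(
                        scaffold, k, config.property_models, rng, latent=latent
                    ),
                    metadata={"Scaffold": scaffold.name, "Substituents": str(k)},
                )
            )
    return Dataset(
        records=records,
        provenance=f"homolog_ladder({scaffold.name}, k={k_min}..{k_max}, seed={seed})",
        global_mz_range=Dataset.infer_range(records),
    )
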