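"""Synthetic salinity-gradient metagenome communities with planted truth.

The generator emulates a brackish-to-marine transect of ~21 samples spanning
0–35 PSU, with the statistical structure the downstream analysis assumes:

* taxa occupy Gaussian salinity niches (optimum μ, breadth σ, baseline weight)
  and carry genomes of different sizes;
* four analogous-pathway pairs (NDH/NQR respiration, MK/UQ quinone synthesis,
  EMP/ED glycolysis, MEP/MVA isoprenoid synthesis) trade off along the
  gradient: each taxon carries exactly one member of each pair, choosing the
  marine member with probability logistic((μ − midpoint)·slope);
* environmental covariates co-vary realistically — temperature rises weakly
  and oxygen falls weakly with salinity, while the N:P ratio, chlorophyll a
  and total phosphorus ride an independent latent axis that also drives a
  cyanobacteria-like taxon group;
* reads are drawn Dirichlet-multinomially with sampling weight proportional
  to abundance × genome size, which is exactly the bias genome-equivalent
  normalization must undo.

All outputs are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import (
    LINEAGE_RANKS,
    AbundanceMatrix,
    EnvTable,
    LineageTable,
    ModuleMap,
)
from .profiles import GenomeEquivalents

__all__ = [
    "Taxon",
    "PathwayPair",
    "GradientSpec",
    "PlantedTruth",
    "DEFAULT_TAXA",
    "DEFAULT_PAIRS",
    "DEFAULT_HOUSEKEEPING",
    "generate_environment",
    "generate_community",
    "generate_functional_profile",
    "planted_signs",
]


@dataclass(frozen=True)
class Taxon:
    """A simulated taxon: Gaussian salinity niche plus genome properties."""

    name: str
    phylum: str
    class_: str
    order: str
    niche_mean: float  # PSU optimum
    niche_sd: float  # PSU niche breadth
    genome_size: float  # bp
    baseline: float = 1.0
    latent_loading: float = 0.0  # response to the secondary (N:P) axis

    def __post_init__(self) -> None:
        if self.niche_sd <= 0:
            raise ValueError(f"{self.name}: niche_sd must be positive")
        if self.genome_size <= 0:
            raise ValueError(f"{self.name}: genome_size must be positive")
        if self.baseline <= 0:
            raise ValueError(f"{self.name}: baseline must be positive")


@dataclass(frozen=True)
class PathwayPair:
    """An analogous-pathway pair trading off along the salinity gradient."""

    fresh_module: str
    marine_module: str
    midpoint: float = 10.0  # PSU at which carriage odds are even
    slope: float = 0.5  # logistic steepness per PSU; 0 removes the link


# Niche optima span the gradient; genome sizes span the 1.2–5.2 Mbp range of
# small streamlined pelagic genomes up to large particle-associated ones.
DEFAULT_TAXA: tuple[Taxon, ...] = (
    Taxon("Polynucleobacter", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", 1.0, 4.0, 2.0e6),
    Taxon("Nanopelagicus", "Actinobacteria", "Actinomycetia", "Nanopelagicales", 2.0, 5.0, 1.4e6),
    Taxon("Limnohabitans", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", 3.0, 4.0, 3.0e6),
    Taxon("Fonsibacter", "Proteobacteria", "Alphaproteobacteria", "Pelagibacterales", 4.0, 5.0, 1.2e6),
    Taxon("Flavobacterium", "Bacteroidetes", "Flavobacteriia", "Flavobacteriales", 5.0, 6.0, 3.5e6),
    Taxon("Limnoluna", "Actinobacteria", "Actinomycetia", "Micrococcales", 6.0, 5.0, 2.4e6),
    Taxon("Algoriphagus", "Bacteroidetes", "Cytophagia", "Cytophagales", 7.0, 6.0, 4.0e6),
    Taxon("Dolichospermum", "Cyanobacteria", "Cyanophyceae", "Nostocales", 8.0, 6.0, 5.2e6, latent_loading=0.8),
    Taxon("Chthoniobacter", "Verrucomicrobia", "Spartobacteria", "Chthoniobacterales", 9.0, 6.0, 4.2e6),
    Taxon("Methylopumilus", "Proteobacteria", "Betaproteobacteria", "Methylophilales", 11.0, 5.0, 1.8e6),
    Taxon("Ilumatobacter", "Actinobacteria", "Acidimicrobiia", "Acidimicrobiales", 12.0, 6.0, 3.2e6),
    Taxon("Synechococcus_br", "Cyanobacteria", "Cyanophyceae", "Synechococcales", 13.0, 7.0, 2.6e6, latent_loading=0.8),
    Taxon("Pelagibacter_IIIa", "Proteobacteria", "Alphaproteobacteria", "Pelagibacterales", 14.0, 6.0, 1.4e6),
    Taxon("Luteolibacter", "Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", 16.0, 6.0, 5.0e6),
    Taxon("Cyanobium", "Cyanobacteria", "Cyanophyceae", "Synechococcales", 18.0, 7.0, 2.8e6, latent_loading=0.8),
    Taxon("SAR92_clade", "Proteobacteria", "Gammaproteobacteria", "Cellvibrionales", 20.0, 6.0, 2.9e6),
    Taxon("Owenweeksia", "Bacteroidetes", "Flavobacteriia", "Flavobacteriales", 22.0, 6.0, 3.4e6),
    Taxon("Pelagibacter_Ia", "Proteobacteria", "Alphaproteobacteria", "Pelagibacterales", 26.0, 6.0, 1.3e6),
    Taxon("Polaribacter", "Bacteroidetes", "Flavobacteriia", "Flavobacteriales", 28.0, 6.0, 3.6e6),
    Taxon("SAR86_clade", "Proteobacteria", "Gammaproteobacteria", "Oceanospirillales", 30.0, 6.0, 2.2e6),
    Taxon("Planktomarina", "Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", 31.0, 6.0, 3.2e6),
    Taxon("Alteromonas", "Proteobacteria", "Gammaproteobacteria", "Alteromonadales", 33.0, 6.0, 4.6e6),
    Taxon("Marinobacter", "Proteobacteria", "Gammaproteobacteria", "Alteromonadales", 34.0, 5.0, 4.3e6),
    Taxon("Sulfitobacter", "Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", 35.0, 5.0, 3.9e6),
)

# KEGG module ids of the four analogous pairs (fresh member first).
DEFAULT_PAIRS: tuple[PathwayPair, ...] = (
    PathwayPair("M00144_NDH", "M00156_NQR"),  # H+- vs Na+-translocating NADH dehydrogenase
    PathwayPair("M00116_MK", "M00117_UQ"),  # menaquinone vs ubiquinone biosynthesis
    PathwayPair("M00001_EMP", "M00008_ED"),  # Embden-Meyerhof vs Entner-Doudoroff glycolysis
    PathwayPair("M00096_MEP", "M00095_MVA"),  # non-mevalonate vs mevalonate isoprenoids
)

#: Core modules carried by every taxon regardless of salinity.
DEFAULT_HOUSEKEEPING: tuple[str, ...] = (
    "M00178_ribosome",
    "M00049_purine",
    "M00082_fatty_acid",
    "M00120_coenzyme_A",
)


@dataclass(frozen=True)
class GradientSpec:
    """Full parameterization of the synthetic salinity-gradient community."""

    n_samples: int = 21
    salinity_min: float = 0.0
    salinity_max: float = 35.0
    salinity_jitter_sd: float = 0.5
    # temperature = intercept + slope·s + N(0, sd)
    temperature_intercept: float = 8.0
    temperature_slope: float = 0.25
    temperature_sd: float = 1.5
    # oxygen = intercept − slope·s + N(0, sd); weak negative relation
    oxygen_intercept: float = 11.0
    oxygen_slope: float = 0.06
    oxygen_sd: float = 1.0
    # N:P, chlorophyll a and total P ride an independent latent axis z ~ N(0,1)
    np_mean: float = 20.0
    np_latent_coeff: float = 8.0
    np_sd: float = 3.0
    chl_log_mean: float = 0.8
    chl_log_latent_coeff: float = -0.5
    chl_log_sd: float = 0.3
    ph_mean: float = 7.9
    ph_sd: float = 0.15
    total_p_mean: float = 0.8
    total_p_latent_coeff: float = -0.12
    total_p_sd: float = 0.1
    taxa: tuple[Taxon, ...] = DEFAULT_TAXA
    pathway_pairs: tuple[PathwayPair, ...] = DEFAULT_PAIRS
    housekeeping_modules: tuple[str, ...] = DEFAULT_HOUSEKEEPING
    kos_per_module: int = 2
    read_depth: int = 50_000
    dirichlet_concentration: float = 50.0
    latent_axis: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.kos_per_module < 1:
            raise ValueError("kos_per_module must be >= 1")
        if not self.taxa:
            raise ValueError("spec needs at least one taxon")
        names = [t.name for t in self.taxa]
        if len(names) != len(set(names)):
            raise ValueError("taxon names must be unique")
        members = [
            m for p in self.pathway_pairs for m in (p.fresh_module, p.marine_module)
        ] + list(self.housekeeping_modules)
        if len(members) != len(set(members)):
            raise ValueError("module ids must be unique across pairs and housekeeping")

    @property
    def modules(self) -> list[str]:
        """All module ids, pair members first, in spec order."""
        out = []
        for pair in self.pathway_pairs:
            out.extend([pair.fresh_module, pair.marine_module])
        out.extend(self.housekeeping_modules)
        return out

    def module_map(self) -> ModuleMap:
        """Deterministic synthetic KO → module map (``kos_per_module`` each)."""
        pairs = []
        ko_counter = 90001
        for module in sorted(self.modules):
            for _ in range(self.kos_per_module):
                pairs.append((f"K{ko_counter:05d}", module))
                ko_counter += 1
        return ModuleMap.from_pairs(pairs)

    def null_variant(self) -> "GradientSpec":
        """Spec with the pathway–salinity link removed (logistic slope 0)."""
        pairs = tuple(replace(p, slope=0.0) for p in self.pathway_pairs)
        return replace(self, pathway_pairs=pairs)


@dataclass
class PlantedTruth:
    """Ground truth of one simulated community.

    ``carriage`` is a taxon × module boolean frame; ``expected_sign`` gives,
    for each module, the expected orientation of its loading on the first
    feature variate relative to salinity (+1 marine member, −1 fresh member,
    0 housekeeping).
    """

    taxa: tuple[Taxon, ...]
    carriage: pd.DataFrame
    expected_sign: dict[str, int]

    def __post_init__(self) -> None:
        pair_cols = [m for m, s in self.expected_sign.items() if s != 0]
        for taxon in self.carriage.index:
            row = self.carriage.loc[taxon, pair_cols]
            # exactly one member of each pair carried
            if int(row.sum()) != len(pair_cols) // 2:
                raise ValueError(f"taxon {taxon!r} violates one-member-per-pair carriage")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def generate_environment(spec: GradientSpec, seed: int) -> EnvTable:
    """Simulate the environmental table for one transect.

    Salinity is equally spaced over the configured range plus jitter (clipped
    at 0); temperature and oxygen are linear in salinity with noise; N:P,
    chlorophyll a and total P are driven by a latent axis independent of
    salinity (stored nowhere — community generation reads it back through the
    observable N:P column).
    """
    rng = _rng(seed, 1)
    n = spec.n_samples
    base = (
        np.linspace(spec.salinity_min, spec.salinity_max, n)
        if n > 1
        else np.array([(spec.salinity_min + spec.salinity_max) / 2])
    )
    salinity = np.clip(base + rng.normal(0, spec.salinity_jitter_sd, n), 0, None)
    temperature = (
        spec.temperature_intercept
        + spec.temperature_slope * salinity
        + rng.normal(0, spec.temperature_sd, n)
    )
    oxygen = (
        spec.oxygen_intercept
        - spec.oxygen_slope * salinity
        + rng.normal(0, spec.oxygen_sd, n)
    )
    z = rng.normal(0, 1, n) if spec.latent_axis else np.zeros(n)
    np_ratio = spec.np_mean + spec.np_latent_coeff * z + rng.normal(0, spec.np_sd, n)
    chl = np.exp(
        spec.chl_log_mean
        + spec.chl_log_latent_coeff * z
        + rng.normal(0, spec.chl_log_sd, n)
    )
    ph = spec.ph_mean + rng.normal(0, spec.ph_sd, n)
    total_p = np.clip(
        spec.total_p_mean
        + spec.total_p_latent_coeff * z
        + rng.normal(0, spec.total_p_sd, n),
        0.01,
        None,
    )
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "station": sample_ids,
            "depth": 5.0,
            "size_fraction": "combined",
            "salinity": salinity,
            "temperature": temperature,
            "oxygen": oxygen,
            "pH": ph,
            "chlorophyll_a": chl,
            "NP_ratio": np_ratio,
            "total_P": total_p,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return EnvTable(frame)


def _lineage_table(taxa: tuple[Taxon, ...]) -> LineageTable:
    rows = {
        t.name: ["Bacteria", t.phylum, t.class_, t.order, t.name] for t in taxa
    }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(LINEAGE_RANKS))
    frame.index.name = "taxon"
    return LineageTable(frame)


def _draw_carriage(
    spec: GradientSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, int]]:
    carriage = pd.DataFrame(
        False, index=[t.name for t in spec.taxa], columns=spec.modules, dtype=bool
    )
    expected: dict[str, int] = {}
    for pair in spec.pathway_pairs:
        expected[pair.fresh_module] = -1
        expected[pair.marine_module] = +1
        p_marine = expit(
            (np.array([t.niche_mean for t in spec.taxa]) - pair.midpoint) * pair.slope
        )
        marine = rng.random(len(spec.taxa)) < p_marine
        carriage[pair.marine_module] = marine
        carriage[pair.fresh_module] = ~marine
    for module in spec.housekeeping_modules:
        carriage[module] = True
        expected[module] = 0
    return carriage, expected


def generate_community(
    spec: GradientSpec, env: EnvTable, seed: int
) -> tuple[AbundanceMatrix, LineageTable, PlantedTruth]:
    """Simulate taxon read counts along the gradient.

    Expected taxon weight at salinity s is baseline·exp(−(s−μ)²/(2σ²)),
    modulated by the latent axis (via the standardized N:P column) for taxa
    with a latent loading.  Per-sample relative abundances are drawn from a
    Dirichlet with concentration ``dirichlet_concentration`` around the
    expected weights; reads are then multinomial with sampling probability
    proportional to abundance × genome size.
    """
    rng = _rng(seed, 2)
    sal = env.env["salinity"].to_numpy()
    if spec.latent_axis and any(t.latent_loading != 0 for t in spec.taxa):
        np_col = env.env["NP_ratio"].to_numpy()
        sd = np_col.std(ddof=1)
        z_proxy = (np_col - np_col.mean()) / sd if sd > 0 else np.zeros_like(np_col)
    else:
        z_proxy = np.zeros_like(sal)
    mu = np.array([t.niche_mean for t in spec.taxa])
    sigma = np.array([t.niche_sd for t in spec.taxa])
    baseline = np.array([t.baseline for t in spec.taxa])
    loading = np.array([t.latent_loading for t in spec.taxa])
    gsize = np.array([t.genome_size for t in spec.taxa])

    weights = baseline[None, :] * np.exp(
        -((sal[:, None] - mu[None, :]) ** 2) / (2 * sigma[None, :] ** 2)
    )
    weights = weights * np.exp(loading[None, :] * z_proxy[:, None])
    row_tot = weights.sum(axis=1)
    if (row_tot <= 0).any():
        bad = env.samples[int(np.argmax(row_tot <= 0))]
        raise ValueError(f"all-zero expected taxon weights at sample {bad!r}")

    counts = np.zeros((len(sal), len(spec.taxa)), dtype=np.int64)
    for i in range(len(sal)):
        alpha = spec.dirichlet_concentration * weights[i] / row_tot[i]
        props = rng.dirichlet(alpha)
        read_p = props * gsize
        read_p = read_p / read_p.sum()
        counts[i] = rng.multinomial(spec.read_depth, read_p)

    frame = pd.DataFrame(
        counts,
        index=pd.Index(env.samples, name="sample_id"),
        columns=[t.name for t in spec.taxa],
    )
    matrix = AbundanceMatrix(frame, "taxon", "raw_counts")
    carriage, expected = _draw_carriage(spec, _rng(seed, 3))
    truth = PlantedTruth(taxa=spec.taxa, carriage=carriage, expected_sign=expected)
    return matrix, _lineage_table(spec.taxa), truth


def generate_functional_profile(
    spec: GradientSpec,
    community: AbundanceMatrix,
    truth: PlantedTruth,
) -> tuple[pd.DataFrame, AbundanceMatrix, GenomeEquivalents]:
    """Derive the functional layer from a simulated community.

    Every read of a taxon carrying a module is annotated to each of the
    module's member KOs, so the per-sample module count is the summed count of
    its carrier taxa.  Genome equivalents are Σ_t count_t·genome_size_t
    divided by the mean genome size of the spec's taxa — the genome-size bias
    that read sampling introduced.
    """
    counts = community.frame
    carriage = truth.carriage.loc[list(counts.columns)].to_numpy()  # T × M
    module_counts = counts.to_numpy() @ carriage  # n × M
    module_frame = pd.DataFrame(
        module_counts.astype(float), index=counts.index, columns=truth.carriage.columns
    )
    modules = AbundanceMatrix(module_frame, "module", "raw_counts")

    mmap = spec.module_map()
    module_kos = {m: mmap.members(m) for m in truth.carriage.columns}
    rows = []
    for taxon in counts.columns:
        carried = [m for m in truth.carriage.columns if truth.carriage.at[taxon, m]]
        for sample in counts.index:
            c = int(counts.at[sample, taxon])
            if c == 0:
                continue
            for module in carried:
                for ko in module_kos[module]:
                    rows.append((sample, taxon, ko, c))
    annotations = pd.DataFrame(rows, columns=["sample_id", "taxon", "KO", "count"])
    # a KO shared by two carried modules would double-count: synthetic KOs are
    # module-private by construction, so keys are unique
    gsize = pd.Series({t.name: t.genome_size for t in spec.taxa})
    ge_values = counts.mul(gsize[counts.columns], axis=1).sum(axis=1) / gsize.mean()
    ge = GenomeEquivalents(ge_values)
    return annotations, modules, ge


def planted_signs(truth: PlantedTruth) -> dict[str, int]:
    """Expected orientation of each module on the first feature variate.

    +1/−1 mark the marine/fresh members of each analogous pair (the two
    members of a pair always sign-oppose); 0 marks housekeeping modules with
    no expected salinity preference.  Depends only on the spec, not the seed.
    """
    return dict(truth.expected_sign)
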