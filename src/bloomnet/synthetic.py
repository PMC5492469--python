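"""Synthetic OTU tables, environmental covariates and random-matrix fixtures
with known ground truth.

The community generator plants block-correlated OTU groups (modules) inside a
compositional count table so that every downstream stage — threshold
selection, network construction, module detection, role classification and
environmental screening — can be validated against a known answer.  Each
module's members share one latent Gaussian factor; mixing weights are chosen
so the latent log-abundance correlation between members hits a stated target.
One focal OTU (a bloom-taxon analogue) is scaled to a stated fraction of the
total community, and counts are drawn per sample by multinomial sampling at a
fixed depth, so every column sum equals the depth exactly.

Random-matrix fixtures provide spectra with known spacing statistics: a GOE
draw (level repulsion) and a diagonal matrix of independent uniforms (Poisson
spacings), used to calibrate the NNSD goodness-of-fit stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import OtuTable, WaterChemistryRecord

__all__ = [
    "CommunityParams",
    "PlantedCommunity",
    "RmtFixture",
    "BACKGROUND_MODULE",
    "generate_planted_community",
    "generate_env_table",
    "generate_rmt_fixture",
    "write_ground_truth",
    "DEFAULT_ENV_BASELINES",
]

#: Module label assigned to unplanted (independent noise) OTUs.
BACKGROUND_MODULE = 0


@dataclass(frozen=True)
class CommunityParams:
    """Generator settings for a planted community.

    Defaults emulate the post-processing product of a 12-sample bloom survey:
    a rarefied depth of 31,736 reads, five planted modules of 30 OTUs inside
    300 OTUs total, a within-module latent correlation of 0.95 and a focal
    bloom taxon holding 60% of the reads (cyanobacterial dominance scale).
    ``latent_sd`` is the log-abundance standard deviation shared by all OTUs;
    ``base_abundance_sd`` spreads planted OTUs' mean log-abundances, while
    ``background_log_mean``/``background_log_sd`` place background OTUs on a
    rank-abundance rare tail so that, as in real rarefied tables, a sizable
    fraction of OTUs falls below the prevalence filter.
    """

    n_samples: int = 12
    n_otus: int = 300
    n_modules: int = 5
    module_size: int = 30
    within_module_correlation: float = 0.95
    depth: int = 31736
    dominance: float = 0.6
    latent_sd: float = 1.0
    base_abundance_sd: float = 1.0
    background_log_mean: float = -6.0
    background_log_sd: float = 2.0
    seed: int = 7


@dataclass
class PlantedCommunity:
    counts: OtuTable
    partition: dict[str, int]       # OTU id -> planted module (0 = background)
    focal_otu: str
    params: CommunityParams

    def module_members(self, module_id: int) -> list[str]:
        return [o for o, m in self.partition.items() if m == module_id]


@dataclass
class RmtFixture:
    matrix: np.ndarray
    kind: str                        # "goe" | "poisson"
    seed: int


def _validate(params: CommunityParams) -> None:
    if params.n_modules * params.module_size > params.n_otus:
        raise ValueError(
            f"n_modules * module_size = {params.n_modules * params.module_size} "
            f"exceeds n_otus = {params.n_otus}"
        )
    if params.depth < 1:
        raise ValueError(f"depth must be >= 1, got {params.depth}")
    if not (0.0 < params.within_module_correlation < 1.0):
        raise ValueError(
            f"within_module_correlation must be in (0, 1), "
            f"got {params.within_module_correlation}"
        )
    if not (0.0 <= params.dominance < 1.0):
        raise ValueError(f"dominance must be in [0, 1), got {params.dominance}")
    if params.n_samples < 2:
        raise ValueError(f"need at least 2 samples, got {params.n_samples}")


def generate_planted_community(params: CommunityParams | None = None) -> PlantedCommunity:
    """Draw one planted community; deterministic under ``params.seed``.

    Latent model per OTU j in module m and sample s:
    ``log w_js = mu_j + sd * (sqrt(rho) f_ms + sqrt(1-rho) eps_js)`` with
    standard-normal factor f and noise eps, so module members correlate at
    rho on the latent log scale; background OTUs carry noise only.  The focal
    OTU (first member of module 1) is rescaled so its expected share of the
    community equals ``dominance``, and counts follow one multinomial draw of
    ``depth`` reads per sample.
    """
    params = params or CommunityParams()
    _validate(params)
    rng = np.random.default_rng(params.seed)
    n, s = params.n_otus, params.n_samples
    rho = params.within_module_correlation

    width = len(str(n))
    otu_ids = [f"OTU{i + 1:0{width}d}" for i in range(n)]
    partition = {o: BACKGROUND_MODULE for o in otu_ids}
    for m in range(params.n_modules):
        for j in range(params.module_size):
            partition[otu_ids[m * params.module_size + j]] = m + 1

    # Planted (module) OTUs sit in the mid-abundance range; background OTUs
    # follow a rank-abundance rare tail, so a realistic fraction of them falls
    # below the prevalence filter downstream (real rarefied tables lose a
    # quarter to a half of their OTUs at an 8-of-12 prevalence cut).
    mu = np.where(
        np.array([partition[o] for o in otu_ids]) == BACKGROUND_MODULE,
        rng.normal(params.background_log_mean, params.background_log_sd, size=n),
        rng.normal(0.0, params.base_abundance_sd, size=n),
    )
    factors = rng.normal(0.0, 1.0, size=(params.n_modules, s))
    eps = rng.normal(0.0, 1.0, size=(n, s))
    latent = np.empty((n, s))
    for i, otu in enumerate(otu_ids):
        m = partition[otu]
        if m == BACKGROUND_MODULE:
            g = eps[i]
        else:
            g = np.sqrt(rho) * factors[m - 1] + np.sqrt(1.0 - rho) * eps[i]
        latent[i] = mu[i] + params.latent_sd * g
    intensity = np.exp(latent)

    focal = otu_ids[0]  # first member of module 1 (or first OTU if no modules)
    if params.dominance > 0:
        others = intensity[1:].sum()
        scale = params.dominance * others / ((1.0 - params.dominance) * intensity[0].sum())
        intensity[0] *= scale

    probs = intensity / intensity.sum(axis=0, keepdims=True)
    counts = np.empty((n, s), dtype=np.int64)
    for j in range(s):
        counts[:, j] = rng.multinomial(params.depth, probs[:, j])

    taxonomy = {}
    for otu in otu_ids:
        m = partition[otu]
        if otu == focal:
            taxonomy[otu] = "Bacteria;Cyanobacteria;Oscillatoriophycideae;Chroococcales;Microcystaceae;Microcystis"
        elif m == BACKGROUND_MODULE:
            taxonomy[otu] = f"Bacteria;BackgroundPhylum;BgClass;BgOrder;BgFamily;Genus_{otu}"
        else:
            taxonomy[otu] = (
                f"Bacteria;ModulePhylum{m};MClass{m};MOrder{m};MFamily{m};Genus_{otu}"
            )

    sample_ids = [f"S{j + 1:02d}" for j in range(s)]
    table = OtuTable(otu_ids, sample_ids, counts, taxonomy)
    return PlantedCommunity(table, partition, focal, params)


#: Baseline magnitudes used by the environmental generator, loosely matching
#: a late-bloom field sheet (units as in WaterChemistryRecord).
DEFAULT_ENV_BASELINES: dict[str, float] = {
    "T": 19.0,
    "DO": 10.5,
    "pH": 9.9,
    "turbidity": 43.0,
    "suspended_particles": 49.0,
    "NO3_N": 0.17,
    "NO2_N": 0.025,
    "NH4_N": 0.27,
    "TN": 2.9,
    "PO4_P": 0.011,
    "COD": 21.0,
    "bacterial_density": 133.0,
    "algal_density": 45.0,
}

LinkSpec = dict[str, str | tuple[int, float]]


def generate_env_table(community: PlantedCommunity, link_spec: LinkSpec | None = None,
                       seed: int = 0, noise_sd: float = 0.3) -> list[WaterChemistryRecord]:
    """Environmental covariates, optionally linked to planted modules.

    ``link_spec`` maps each variable name to ``"independent"`` or a
    ``(module_id, effect_size)`` pair.  A linked variable is a monotone
    (log-linear) function of the standardized total relative abundance of its
    module plus lognormal noise; independent variables are pure lognormal
    noise around their baseline.  One record per sample.
    """
    link_spec = dict(link_spec or {})
    for var in link_spec:
        if var not in DEFAULT_ENV_BASELINES:
            raise ValueError(f"unknown environmental variable {var!r}")
    table = community.counts
    rel = table.counts / table.counts.sum(axis=0, keepdims=True)
    module_z: dict[int, np.ndarray] = {}
    valid_modules = set(community.partition.values()) - {BACKGROUND_MODULE}
    idx_of = {o: i for i, o in enumerate(table.otu_ids)}
    for m in valid_modules:
        rows = [idx_of[o] for o in community.module_members(m)]
        total = rel[rows].sum(axis=0)
        sd = total.std()
        module_z[m] = (total - total.mean()) / sd if sd > 0 else np.zeros_like(total)

    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for var, baseline in DEFAULT_ENV_BASELINES.items():
        spec = link_spec.get(var, "independent")
        noise = rng.normal(0.0, 1.0, size=table.n_samples)
        if spec == "independent":
            values[var] = baseline * np.exp(noise_sd * noise)
        else:
            module_id, effect = spec
            if module_id not in module_z:
                raise ValueError(f"unknown module id {module_id!r} for variable {var!r}")
            values[var] = baseline * np.exp(effect * module_z[module_id] + noise_sd * noise)

    records = []
    for j, sample in enumerate(table.sample_ids):
        records.append(WaterChemistryRecord(
            sample_id=sample,
            **{var: float(values[var][j]) for var in DEFAULT_ENV_BASELINES},
        ))
    return records


def generate_rmt_fixture(kind: str, n: int, seed: int) -> RmtFixture:
    """Random-matrix fixture with known spacing statistics.

    ``goe``: symmetrized Gaussian matrix (off-diagonal variance half the
    diagonal's) whose unfolded spacings follow the Wigner surmise.
    ``poisson``: diagonal matrix of independent uniforms, whose eigenvalues
    are independent and give exponential (Poisson) spacings.
    """
    if kind not in ("goe", "poisson"):
        raise ValueError(f"kind must be 'goe' or 'poisson', got {kind!r}")
    if n < 50:
        raise ValueError(f"n must be >= 50, got {n}")
    rng = np.random.default_rng(seed)
    if kind == "goe":
        a = rng.normal(0.0, 1.0, size=(n, n))
        matrix = (a + a.T) / 2.0
    else:
        matrix = np.diag(rng.uniform(0.0, 1.0, size=n))
    return RmtFixture(matrix, kind, seed)


def write_ground_truth(community: PlantedCommunity, path: str | Path) -> None:
    """Write the planted partition as a two-column TSV (otu_id, module_id)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\tmodule_id\n")
        for otu in community.counts.otu_ids:
            fh.write(f"{otu}\t{community.partition[otu]}\n")
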