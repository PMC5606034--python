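"""Synthetic two-diet rumen studies with known planted structure.

The generator emulates the design every downstream stage expects: two diet
groups (low vs medium non-fiber carbohydrate, ``LC`` / ``MC``) of a few
animals each, an overdispersed 16S OTU count table, an epithelial
expression matrix seeded with GPR/HDAC-like genes, and a four-time-point
SCFA concentration series.  A shared latent per-sample butyrate molar
proportion drives both the SCFA table and the "producer" OTUs, planting the
taxon-metabolite-gene covariation the integration stage must recover; a
:class:`SyntheticTruth` object indexes every planted feature.

Counts are Dirichlet-multinomial at fixed depth; expression is built
additively on the log2 scale (baselines + group effects + shared block
factors + Gaussian noise) and exponentiated, so RPKM is nonnegative and
planted co-expression blocks are exactly monotone when the noise is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .abundance import OtuTable
from .errors import ConfigurationError
from .expression import ExpressionMatrix
from .integration import SCFAS, ScfaProfile

#: Seed genes with their family and planted regulation direction in MC,
#: mirroring the receptor/deacetylase panel of a two-diet rumen study.
SEED_GENE_PANEL = (
    ("GPR1", "GPR", +1),
    ("GPR87", "GPR", +1),
    ("GPR89A", "GPR", +1),
    ("GPR155", "GPR", +1),
    ("GPR107", "GPR", -1),
    ("FFAR4", "GPR", -1),
    ("HCAR2", "GPR", -1),
    ("HDAC1", "HDAC", -1),
    ("HDAC4", "HDAC", +1),
    ("HDAC5", "HDAC", +1),
    ("HDAC6", "HDAC", +1),
    ("HDAC10", "HDAC", +1),
)

_PHYLA = (
    "Firmicutes", "Bacteroidetes", "Synergistetes", "Proteobacteria",
    "Tenericutes", "Fibrobacteres", "Lentisphaerae", "Actinobacteria",
)

#: Baseline molar proportions of the six SCFAs in ruminal fluid.
_BASE_PROPORTIONS = np.array([0.65, 0.20, 0.10, 0.02, 0.012, 0.018])

#: Baseline total SCFA (mmol/L) and pH by hours after morning feeding.
_BASE_TOTAL = {0: 70.0, 2: 95.0, 5: 90.0, 8: 72.0}
_BASE_PH = {0: 6.9, 2: 6.3, 5: 6.45, 8: 6.7}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a simulated two-diet experiment.

    Defaults follow the emulated design: 3 animals per group, a few hundred
    OTUs at 50k reads per sample, 200 genes including the 12-gene GPR/HDAC
    panel, and effect sizes at the magnitude a medium-NFC diet induces.
    ``recovery()`` gives the well-powered 20-per-group preset used for
    planted-structure recovery checks.
    """

    seed: int = 0
    n_per_group: int = 3
    n_otus: int = 300
    n_genera: int = 40
    n_genes: int = 200
    n_seed_genes: int = 12
    block_size: int = 4  # planted co-expression neighbours per seed gene
    sequencing_depth: int = 50_000
    # planted effect sizes
    taxon_shift_log2fc: float = 1.5
    n_shifted_otus: int = 20
    de_log2fc: float = 3.0
    scfa_total_delta: float = 25.0  # mmol/L added to MC totals at 2 and 5 h
    butyrate_prop_delta: float = 0.05
    ph_delta: float = 0.25  # MC pH shift at 5 h
    producer_coupling: float = 1.5  # log-abundance slope per latent z-score
    latent_coupling: float = 1.0  # HDAC1/GPR1 log2-expression slope per z
    n_producer_otus: int = 10
    # noise
    dispersion: float = 300.0  # Dirichlet concentration (higher = tighter)
    noise_sd: float = 0.25  # expression log2 noise
    block_factor_sd: float = 1.0  # sd of the shared co-expression block factor
    proportion_noise: float = 0.15  # per-sample SCFA proportion jitter (log scale)
    group_names: tuple = ("LC", "MC")

    def validate(self) -> None:
        positive = {
            "n_per_group": self.n_per_group, "n_otus": self.n_otus,
            "n_genera": self.n_genera, "n_genes": self.n_genes,
            "sequencing_depth": self.sequencing_depth, "dispersion": self.dispersion,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        for name in ("n_seed_genes", "block_size", "n_producer_otus",
                     "n_shifted_otus", "noise_sd", "proportion_noise",
                     "block_factor_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.n_producer_otus > self.n_otus:
            raise ConfigurationError("n_producer_otus cannot exceed n_otus")
        if self.n_producer_otus + self.n_shifted_otus > self.n_otus:
            raise ConfigurationError("producer + shifted OTUs cannot exceed n_otus")
        if self.n_otus - self.n_producer_otus < self.n_genera - 1:
            raise ConfigurationError("too few OTUs to populate every genus")
        if self.n_seed_genes * (1 + self.block_size) > self.n_genes:
            raise ConfigurationError("seed blocks do not fit into n_genes")
        effects = (self.taxon_shift_log2fc, self.de_log2fc, self.scfa_total_delta,
                   self.butyrate_prop_delta, self.producer_coupling,
                   self.latent_coupling, self.ph_delta)
        if not all(math.isfinite(v) for v in effects):
            raise ConfigurationError("effect sizes must be finite")
        if len(self.group_names) != 2:
            raise ConfigurationError("exactly two group names required")

    @classmethod
    def recovery(cls, **overrides) -> "SyntheticConfig":
        """Well-powered preset (20 animals per group) for recovery checks."""
        overrides.setdefault("n_per_group", 20)
        return cls(**overrides)


@dataclass(frozen=True)
class SyntheticTruth:
    """Index of every planted feature of a simulated study."""

    planted_de_genes: frozenset
    de_directions: dict  # gene -> +1 (up in MC) | -1
    planted_edges: frozenset  # frozenset of sorted gene pairs
    producer_otus: frozenset
    planted_taxon_shifts: dict  # otu -> +1 | -1
    scfa_group_effects: dict  # effect name -> delta

    def to_dict(self) -> dict:
        return {
            "planted_de_genes": sorted(self.planted_de_genes),
            "de_directions": dict(sorted(self.de_directions.items())),
            "planted_edges": sorted(sorted(e) for e in self.planted_edges),
            "producer_otus": sorted(self.producer_otus),
            "planted_taxon_shifts": dict(sorted(self.planted_taxon_shifts.items())),
            "scfa_group_effects": self.scfa_group_effects,
        }


@dataclass(frozen=True)
class SimulatedStudy:
    otu_table: OtuTable
    expression: ExpressionMatrix
    scfa: ScfaProfile
    truth: SyntheticTruth


def sample_groups(cfg: SyntheticConfig) -> pd.Series:
    """Deterministic sample ids and group labels for a configuration."""
    g1, g2 = cfg.group_names
    ids = [f"{g1}{i + 1}" for i in range(cfg.n_per_group)] + [
        f"{g2}{i + 1}" for i in range(cfg.n_per_group)
    ]
    labels = [g1] * cfg.n_per_group + [g2] * cfg.n_per_group
    return pd.Series(labels, index=ids, name="group")


def _seed_gene_names(cfg: SyntheticConfig) -> list[tuple]:
    panel = list(SEED_GENE_PANEL[: cfg.n_seed_genes])
    extra = cfg.n_seed_genes - len(panel)
    for i in range(extra):
        family = "GPR" if i % 2 == 0 else "HDAC"
        panel.append((f"{family}{200 + i}", family, +1 if i % 2 == 0 else -1))
    return panel


def simulate_scfa(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[ScfaProfile, pd.Series]:
    """SCFA concentration series plus the latent butyrate molar proportion.

    Per-sample molar proportions are drawn once and held approximately
    constant across time; totals follow a postprandial curve with the planted
    MC increase at 2 and 5 h, so acetate/butyrate/total concentrations rise
    together in MC.  The MC butyrate proportion is shifted up by
    ``butyrate_prop_delta``.  All concentrations are strictly positive.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[0])
    groups = sample_groups(cfg)
    n = len(groups)
    mc = cfg.group_names[1]

    props = _BASE_PROPORTIONS * np.exp(
        rng.normal(0.0, cfg.proportion_noise, size=(n, len(SCFAS)))
    )
    props /= props.sum(axis=1, keepdims=True)
    but = list(SCFAS).index("butyrate")
    props[(groups == mc).to_numpy(), but] += cfg.butyrate_prop_delta
    props /= props.sum(axis=1, keepdims=True)
    latent = pd.Series(props[:, but], index=groups.index, name="butyrate_proportion")

    sample_offset = rng.normal(0.0, 5.0, size=n)
    rows = []
    for t in sorted(_BASE_TOTAL):
        total = _BASE_TOTAL[t] + sample_offset + rng.normal(0.0, 3.0, size=n)
        if t in (2, 5):
            total = total + cfg.scfa_total_delta * (groups == mc).to_numpy()
        total = np.clip(total, 10.0, None)
        conc = total[:, None] * props * np.exp(rng.normal(0.0, 0.03, size=props.shape))
        conc = np.clip(conc, 1e-6, None)
        ph = _BASE_PH[t] + rng.normal(0.0, 0.08, size=n)
        if t == 5:
            ph = ph + cfg.ph_delta * (groups == mc).to_numpy()
        for i, sid in enumerate(groups.index):
            rows.append(
                {"sample": sid, "time_h": t,
                 **{s: conc[i, k] for k, s in enumerate(SCFAS)}, "pH": ph[i]}
            )
    profile = ScfaProfile(data=pd.DataFrame(rows), groups=groups)
    return profile, latent


def _taxonomy(cfg: SyntheticConfig, genus_idx: np.ndarray) -> pd.DataFrame:
    genera = ["Clostridium_IV", "Prevotella"] + [
        f"Genus_{i:02d}" for i in range(2, cfg.n_genera)
    ]
    phyla = {g: _PHYLA[i % len(_PHYLA)] for i, g in enumerate(genera)}
    phyla["Clostridium_IV"] = "Firmicutes"
    phyla["Prevotella"] = "Bacteroidetes"
    families = {g: f"Family_{i // 2:02d}" for i, g in enumerate(genera)}
    families["Clostridium_IV"] = "Ruminococcaceae"
    families["Prevotella"] = "Prevotellaceae"
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(cfg.n_otus)]
    rows = []
    n_unclassified = cfg.n_otus // 10
    for i, otu in enumerate(otu_ids):
        g = genera[genus_idx[i]]
        if i >= cfg.n_otus - n_unclassified and genus_idx[i] != 0:
            rows.append({"phylum": phyla[g], "family": families[g], "genus": None})
        else:
            rows.append({"phylum": phyla[g], "family": families[g], "genus": g})
    return pd.DataFrame(rows, index=otu_ids)


def simulate_microbiome(
    cfg: SyntheticConfig, latent: pd.Series, rng: np.random.Generator | None = None
) -> OtuTable:
    """Dirichlet-multinomial OTU counts at fixed sequencing depth.

    Producer OTUs (assigned to the Clostridium_IV genus) have expected
    relative abundance increasing monotonically with the latent butyrate
    proportion; group-shifted OTUs have their expected abundance multiplied
    by the planted fold change in the MC group.
    """
    table, _ = _simulate_microbiome(cfg, latent, rng)
    return table


def _simulate_microbiome(
    cfg: SyntheticConfig, latent: pd.Series, rng: np.random.Generator | None = None
) -> tuple[OtuTable, dict]:
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[1])
    groups = sample_groups(cfg)
    if not set(groups.index) <= set(latent.index):
        raise ConfigurationError("latent series must cover every sample")
    n = len(groups)
    mc = cfg.group_names[1]

    n_prod = cfg.n_producer_otus
    genus_idx = np.zeros(cfg.n_otus, dtype=int)
    rest = cfg.n_otus - n_prod
    genus_idx[n_prod:] = 1 + (np.arange(rest) % max(cfg.n_genera - 1, 1))
    taxonomy = _taxonomy(cfg, genus_idx)
    otu_ids = list(taxonomy.index)

    alpha = rng.lognormal(mean=0.0, sigma=1.5, size=cfg.n_otus)
    alpha[:n_prod] = rng.lognormal(mean=2.0, sigma=0.3, size=n_prod)

    shifted = rng.choice(
        np.arange(n_prod, cfg.n_otus), size=cfg.n_shifted_otus, replace=False
    )
    directions = np.where(np.arange(cfg.n_shifted_otus) % 2 == 0, 1, -1)

    z = latent.reindex(groups.index).to_numpy(float)
    z = (z - z.mean()) / z.std() if z.std() > 0 else np.zeros_like(z)
    is_mc = (groups == mc).to_numpy()

    counts = np.zeros((n, cfg.n_otus), dtype=int)
    for s in range(n):
        mean = alpha.copy()
        mean[:n_prod] *= np.exp(cfg.producer_coupling * z[s])
        if is_mc[s]:
            mean[shifted] *= 2.0 ** (directions * cfg.taxon_shift_log2fc)
        p = mean / mean.sum()
        q = rng.dirichlet(cfg.dispersion * p)
        counts[s] = rng.multinomial(cfg.sequencing_depth, q)
    frame = pd.DataFrame(counts, index=groups.index, columns=otu_ids)
    shifts = {
        otu_ids[i]: int(directions[j]) for j, i in enumerate(shifted)
    }
    return OtuTable(counts=frame, taxonomy=taxonomy, groups=groups), shifts


def simulate_transcriptome(
    cfg: SyntheticConfig,
    latent: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Log-scale additive expression model exponentiated to RPKM.

    Seed genes carry the planted group effect (direction per panel entry);
    each seed gene shares one latent block factor with its planted
    co-expression neighbours, which also inherit the group effect (so
    neighbours are differentially expressed, as the seed-neighbourhood
    analysis expects).  When ``latent`` is given, HDAC1 is coupled
    negatively and GPR1 positively to the standardised butyrate proportion.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    groups = sample_groups(cfg)
    n = len(groups)
    is_mc = (groups == cfg.group_names[1]).to_numpy().astype(float)

    panel = _seed_gene_names(cfg)
    seed_names = [name for name, _, _ in panel]
    n_members = cfg.n_seed_genes * cfg.block_size
    member_names = [f"GENE_{i + 1:04d}" for i in range(n_members)]
    other_names = [
        f"GENE_{i + 1:04d}" for i in range(n_members, cfg.n_genes - cfg.n_seed_genes)
    ]
    gene_ids = seed_names + member_names + other_names
    families = pd.Series(
        [fam for _, fam, _ in panel] + ["other"] * (len(gene_ids) - len(panel)),
        index=gene_ids,
    )

    baseline = rng.normal(4.0, 1.5, size=len(gene_ids))
    log2 = np.tile(baseline[:, None], (1, n))

    if latent is not None:
        z = latent.reindex(groups.index).to_numpy(float)
        z = (z - z.mean()) / z.std() if z.std() > 0 else np.zeros_like(z)
    else:
        z = None

    for k, (name, _, direction) in enumerate(panel):
        factor = rng.normal(0.0, cfg.block_factor_sd, size=n)
        block = [name] + member_names[k * cfg.block_size : (k + 1) * cfg.block_size]
        for gene in block:
            gi = gene_ids.index(gene)
            log2[gi] += direction * cfg.de_log2fc * is_mc + factor
        if z is not None and name == "HDAC1":
            log2[gene_ids.index(name)] += -cfg.latent_coupling * z
        if z is not None and name == "GPR1":
            log2[gene_ids.index(name)] += cfg.latent_coupling * z

    log2 += rng.normal(0.0, cfg.noise_sd, size=log2.shape)
    rpkm_values = pd.DataFrame(2.0**log2, index=gene_ids, columns=groups.index)
    return ExpressionMatrix(rpkm=rpkm_values, families=families, groups=groups)


def _planted_edges(cfg: SyntheticConfig) -> frozenset:
    panel = _seed_gene_names(cfg)
    member_names = [f"GENE_{i + 1:04d}" for i in range(cfg.n_seed_genes * cfg.block_size)]
    edges = set()
    for k, (name, _, _) in enumerate(panel):
        block = [name] + member_names[k * cfg.block_size : (k + 1) * cfg.block_size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                edges.add(frozenset((block[i], block[j])))
    return frozenset(edges)


def simulate_study(cfg: SyntheticConfig) -> SimulatedStudy:
    """Compose the three generators off one seed.

    Sub-generators draw from independent child streams of ``cfg.seed``, so
    e.g. changing ``n_genes`` does not perturb the microbiome draw.
    """
    cfg.validate()
    children = np.random.SeedSequence(cfg.seed).spawn(3)
    scfa, latent = simulate_scfa(cfg, np.random.default_rng(children[0]))
    otu_table, shifted = _simulate_microbiome(
        cfg, latent, np.random.default_rng(children[1])
    )
    expression = simulate_transcriptome(cfg, latent, np.random.default_rng(children[2]))

    panel = _seed_gene_names(cfg)
    n_members = cfg.n_seed_genes * cfg.block_size
    member_names = [f"GENE_{i + 1:04d}" for i in range(n_members)]
    de_directions = {name: d for name, _, d in panel}
    for k, (name, _, d) in enumerate(panel):
        for gene in member_names[k * cfg.block_size : (k + 1) * cfg.block_size]:
            de_directions[gene] = d
    producer = frozenset(otu_table.otu_ids[: cfg.n_producer_otus])
    truth = SyntheticTruth(
        planted_de_genes=frozenset(de_directions),
        de_directions=de_directions,
        planted_edges=_planted_edges(cfg),
        producer_otus=producer,
        planted_taxon_shifts=shifted,
        scfa_group_effects={
            "total_delta_2_5h": cfg.scfa_total_delta,
            "butyrate_proportion_delta": cfg.butyrate_prop_delta,
            "ph_delta_5h": cfg.ph_delta,
        },
    )
    return SimulatedStudy(otu_table=otu_table, expression=expression, scfa=scfa, truth=truth)
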