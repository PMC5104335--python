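"""Synthetic expression datasets and promoter sequences with known truth.

The generator emulates the structure the pipeline assumes: 2 genotypes
x 5 timepoints x 3 replicates of strictly positive intensities with
log-normal noise, negative-control probes, multi-probe genes,
low-quality probes, four temporal archetypes, latent-factor
co-expression modules with designated hubs, genotype-specific fold
changes, and promoters with planted motif occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from somhub.io_formats import (
    ExpressionMatrix,
    GENOTYPES,
    ProbeAnnotation,
    Pwm,
    SampleDescriptor,
    TIMEPOINTS,
    ValidationError,
)

ARCHETYPES = ("neonatal", "juvenile", "adult", "flat")

# log2-scale temporal shapes over (P1, P7, P14, P30, P60); chosen so the
# z-scored curve is classified as its own stage by the cluster
# categorizer (flat has zero amplitude and lands in "atypical").
ARCHETYPE_CURVES: dict[str, np.ndarray] = {
    "neonatal": np.array([2.0, 1.0, 0.0, -1.0, -2.0]),
    "juvenile": np.array([-1.0, 1.5, 1.0, -0.5, -1.0]),
    "adult": np.array([-1.5, -1.2, -0.5, 1.3, 1.9]),
    "flat": np.zeros(5),
}

# fixed sub-seed offsets per generator component (single seeded stream
# per dataset would couple unrelated draws across config changes)
_OFFSETS = {"archetype": 1, "module": 2, "noise": 3, "negctl": 4, "probes": 5}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class ModuleSpec:
    size: int
    hub_loading: float
    member_loading: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ConfigError("module size must be >= 2")
        if not 0 < self.hub_loading <= 1:
            raise ConfigError("hub_loading must be in (0, 1]")
        if not 0 < self.member_loading < 1:
            raise ConfigError("member_loading must be in (0, 1)")


@dataclass(frozen=True)
class KoEffect:
    gene: str
    timepoint: str
    fold_change: float

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ConfigError(f"unknown timepoint {self.timepoint!r}")
        if not (np.isfinite(self.fold_change) and self.fold_change > 0):
            raise ConfigError("fold_change must be finite and positive")


@dataclass
class SimulationConfig:
    n_genes: int = 200
    n_negative_controls: int = 20
    archetype_fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    modules: tuple[ModuleSpec, ...] = ()
    ko_effects: tuple[KoEffect, ...] = ()
    noise_sd_log2: float = 0.25
    multi_probe_fraction: float = 0.1
    bad_probe_fraction: float = 0.05
    base_log2_mean: float = 8.0
    base_log2_sd: float = 1.0
    # negative controls: mean + 2 sd sits below the 5th percentile of
    # true signal by default, so background filtering is testable in
    # both directions
    negctl_log2_mean: float = 3.0
    negctl_log2_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = np.asarray(self.archetype_fractions, dtype=float)
        if fractions.shape != (4,) or (fractions < 0).any():
            raise ConfigError("archetype_fractions must be 4 nonnegative reals")
        if not np.isclose(fractions.sum(), 1.0, atol=1e-9):
            raise ConfigError("archetype_fractions must sum to 1")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ConfigError("module sizes exceed n_genes")
        if self.noise_sd_log2 <= 0:
            raise ConfigError("noise_sd_log2 must be positive")
        for frac_name in ("multi_probe_fraction", "bad_probe_fraction"):
            value = getattr(self, frac_name)
            if not 0 <= value <= 1:
                raise ConfigError(f"{frac_name} must be in [0, 1]")


@dataclass
class GroundTruth:
    archetype: dict[str, str]
    module_members: dict[int, tuple[str, ...]]
    hub_genes: dict[int, str]
    ko_effects: tuple[KoEffect, ...]
    probe_to_gene: dict[str, str]

    def probes_for(self, gene: str) -> list[str]:
        return [p for p, g in self.probe_to_gene.items() if g == gene]


def _make_samples(genotype: str) -> list[SampleDescriptor]:
    return [
        SampleDescriptor(f"{genotype}_{tp}_r{rep}", genotype, tp, rep)
        for tp in TIMEPOINTS
        for rep in (1, 2, 3)
    ]


def generate_expression(
    config: SimulationConfig,
) -> tuple[dict[str, ExpressionMatrix], ProbeAnnotation, GroundTruth]:
    """Simulate raw intensity matrices per genotype plus annotation/truth.

    Per gene g and timepoint t the log2 mean is an archetype curve plus
    a latent-factor module contribution (one standard-normal factor
    value per sample; members add loading*z, the designated hub uses its
    higher hub loading).  KO samples multiply the linear mean by the
    configured fold change at affected (gene, timepoint) pairs.  The
    observation is 2**(mu + eps) with eps ~ N(0, noise_sd_log2).
    """
    rng_arch = np.random.default_rng(config.seed + _OFFSETS["archetype"])
    rng_module = np.random.default_rng(config.seed + _OFFSETS["module"])
    rng_noise = np.random.default_rng(config.seed + _OFFSETS["noise"])
    rng_negctl = np.random.default_rng(config.seed + _OFFSETS["negctl"])
    rng_probes = np.random.default_rng(config.seed + _OFFSETS["probes"])

    n = config.n_genes
    genes = [f"G{i:05d}" for i in range(1, n + 1)]
    n_module_genes = sum(m.size for m in config.modules)

    # module genes occupy the head of the gene list and share one
    # archetype per module (cycled over the stage shapes) so each
    # co-expression module lives inside one temporal cluster; the
    # remaining genes follow the configured archetype fractions
    labels = np.empty(n, dtype=int)
    cursor0 = 0
    for m_idx, module in enumerate(config.modules):
        labels[cursor0 : cursor0 + module.size] = m_idx % 3
        cursor0 += module.size
    n_free = n - n_module_genes
    fractions = np.asarray(config.archetype_fractions, dtype=float)
    counts = np.floor(fractions * n_free).astype(int)
    while counts.sum() < n_free:
        counts[int(np.argmax(fractions * n_free - counts))] += 1
    free_labels = np.repeat(np.arange(4), counts)
    rng_arch.shuffle(free_labels)
    labels[n_module_genes:] = free_labels
    archetype = {g: ARCHETYPES[a] for g, a in zip(genes, labels)}

    base = rng_arch.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    curve = np.stack([ARCHETYPE_CURVES[archetype[g]] for g in genes])  # n x 5

    samples = {gt: _make_samples(gt) for gt in GENOTYPES}
    n_samples = len(samples["control"])
    tp_index = {tp: i for i, tp in enumerate(TIMEPOINTS)}

    # module structure: contiguous gene blocks, first member is the hub
    loadings = np.zeros(n)
    factor_of_gene = np.full(n, -1)
    module_members: dict[int, tuple[str, ...]] = {}
    hub_genes: dict[int, str] = {}
    cursor = 0
    for m_idx, module in enumerate(config.modules):
        block = list(range(cursor, cursor + module.size))
        cursor += module.size
        module_members[m_idx] = tuple(genes[i] for i in block)
        hub_genes[m_idx] = genes[block[0]]
        loadings[block] = module.member_loading
        loadings[block[0]] = module.hub_loading
        factor_of_gene[block] = m_idx

    gene_index = {g: i for i, g in enumerate(genes)}
    ko_by_gene_tp = {(e.gene, e.timepoint): e.fold_change for e in config.ko_effects}
    unknown = [e.gene for e in config.ko_effects if e.gene not in set(genes)]
    if unknown:
        raise ConfigError(f"ko_effects reference unknown genes {unknown}")

    matrices: dict[str, ExpressionMatrix] = {}
    annotation_rows: list[dict] = []
    probe_to_gene: dict[str, str] = {}

    # probe layout decided once, shared by both genotypes
    probe_ids = [f"ILMN_{g}" for g in genes]
    n_multi = int(np.floor(config.multi_probe_fraction * n))
    multi_idx = np.sort(rng_probes.choice(n, size=n_multi, replace=False))
    secondary_ids = [f"ILMN_{genes[i]}_2" for i in multi_idx]
    # low-quality probes are extra rows so flagged quality never removes
    # a gene's sole measurement
    n_bad = int(np.floor(config.bad_probe_fraction * (n + n_multi)))
    bad_gene_idx = rng_probes.choice(n, size=n_bad, replace=True)
    bad_ids = [f"ILMN_BAD_{k:04d}" for k in range(n_bad)]
    negctl_ids = [f"NEG_{k:04d}" for k in range(config.n_negative_controls)]

    for g, p in zip(genes, probe_ids):
        probe_to_gene[p] = g
        annotation_rows.append(
            {"probe_id": p, "gene_symbol": g, "quality": "good", "is_negative_control": False}
        )
    for i, p in zip(multi_idx, secondary_ids):
        probe_to_gene[p] = genes[i]
        annotation_rows.append(
            {"probe_id": p, "gene_symbol": genes[i], "quality": "good", "is_negative_control": False}
        )
    for gi, p in zip(bad_gene_idx, bad_ids):
        probe_to_gene[p] = genes[gi]
        annotation_rows.append(
            {"probe_id": p, "gene_symbol": genes[gi], "quality": "bad", "is_negative_control": False}
        )
    for p in negctl_ids:
        annotation_rows.append(
            {"probe_id": p, "gene_symbol": "", "quality": "good", "is_negative_control": True}
        )

    for genotype in GENOTYPES:
        descriptors = samples[genotype]
        mu = np.empty((n, n_samples))
        factors = rng_module.normal(size=(max(len(config.modules), 1), n_samples))
        for s_idx, descriptor in enumerate(descriptors):
            t = tp_index[descriptor.timepoint]
            col = base + curve[:, t]
            if len(config.modules):
                has_module = factor_of_gene >= 0
                col = col + np.where(
                    has_module, loadings * factors[factor_of_gene, s_idx], 0.0
                )
            if genotype == "ko":
                for (gene, tp), fc in ko_by_gene_tp.items():
                    if tp == descriptor.timepoint:
                        col[gene_index[gene]] += np.log2(fc)
            mu[:, s_idx] = col
        eps = rng_noise.normal(0.0, config.noise_sd_log2, size=(n, n_samples))
        signal = 2.0 ** (mu + eps)

        secondary = 2.0 ** (
            mu[multi_idx] - 1.0
            + rng_noise.normal(0.0, config.noise_sd_log2, size=(n_multi, n_samples))
        )
        bad = 2.0 ** (
            mu[bad_gene_idx] - 2.0
            + rng_noise.normal(0.0, config.noise_sd_log2, size=(n_bad, n_samples))
        )
        negctl = 2.0 ** rng_negctl.normal(
            config.negctl_log2_mean,
            config.negctl_log2_sd,
            size=(config.n_negative_controls, n_samples),
        )

        values = np.vstack([signal, secondary, bad, negctl])
        index = probe_ids + secondary_ids + bad_ids + negctl_ids
        frame = pd.DataFrame(values, index=index, columns=[s.sample_id for s in descriptors])
        matrices[genotype] = ExpressionMatrix(frame, descriptors)

    annotation = ProbeAnnotation(pd.DataFrame(annotation_rows).set_index("probe_id"))
    truth = GroundTruth(
        archetype=archetype,
        module_members=module_members,
        hub_genes=hub_genes,
        ko_effects=tuple(config.ko_effects),
        probe_to_gene=probe_to_gene,
    )
    return matrices, annotation, truth


def one_factor_module(
    n_genes: int = 20,
    n_samples: int = 15,
    hub_loading: float = 0.95,
    member_loading: float = 0.5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], int]:
    """Pure one-factor co-expression module for network benchmarking.

    Gene 0 is the designated hub.  Each gene is
    x_g = loading_g * z + noise_sd * sqrt(1 - loading_g^2) * eps
    with a shared standard-normal factor value z per sample, so the
    idiosyncratic noise shrinks as the loading grows (factor-model
    convention) and ``noise_sd`` scales it globally.  Returns
    (expression, gene ids, hub index).
    """
    rng = np.random.default_rng(seed)
    loadings = np.full(n_genes, member_loading)
    loadings[0] = hub_loading
    z = rng.normal(size=n_samples)
    eps = rng.normal(size=(n_genes, n_samples))
    idio = noise_sd * np.sqrt(1.0 - loadings**2)
    expr = loadings[:, None] * z[None, :] + idio[:, None] * eps
    gene_ids = [f"G{i:03d}" for i in range(n_genes)]
    return expr, gene_ids, 0


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


@dataclass
class PromoterTruth:
    planted_fg: dict[str, tuple[int, str]] = field(default_factory=dict)
    planted_bg: dict[str, tuple[int, str]] = field(default_factory=dict)


def _sample_motif_instance(pwm: Pwm, rng: np.random.Generator) -> str:
    bases = []
    for col in pwm.probs.T:
        bases.append("ACGT"[rng.choice(4, p=col / col.sum())])
    return "".join(bases)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_promoters(
    n_fg: int,
    n_bg: int,
    length: int,
    pwm: Pwm,
    planted_fraction_fg: float,
    planted_fraction_bg: float,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], PromoterTruth]:
    """Simulate foreground/background promoter sets with planted motifs.

    Backgrounds are i.i.d. draws from the PWM background frequencies; a
    planted sequence receives one motif occurrence sampled from the PWM
    columns, placed at a uniform random position on a uniform random
    strand and recorded in the returned truth.
    """
    for name, value in (("planted_fraction_fg", planted_fraction_fg),
                        ("planted_fraction_bg", planted_fraction_bg)):
        if not 0 <= value <= 1:
            raise ConfigError(f"{name} must be in [0, 1]")
    if length < pwm.length:
        raise ConfigError("sequence length shorter than motif")
    rng = np.random.default_rng(seed)
    truth = PromoterTruth()

    def build(prefix: str, count: int, fraction: float, planted_store: dict) -> dict[str, str]:
        records: dict[str, str] = {}
        n_planted = int(round(fraction * count))
        planted = set(rng.choice(count, size=n_planted, replace=False)) if n_planted else set()
        for i in range(count):
            seq = "".join(
                "ACGT"[b] for b in rng.choice(4, size=length, p=pwm.background)
            )
            seq_id = f"{prefix}_{i:04d}"
            if i in planted:
                instance = _sample_motif_instance(pwm, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    instance = reverse_complement(instance)
                pos = int(rng.integers(0, length - pwm.length + 1))
                seq = seq[:pos] + instance + seq[pos + pwm.length:]
                planted_store[seq_id] = (pos, strand)
            records[seq_id] = seq
        return records

    fg = build("fg", n_fg, planted_fraction_fg, truth.planted_fg)
    bg = build("bg", n_bg, planted_fraction_bg, truth.planted_bg)
    return fg, bg, truth
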