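"""Synthetic pipeline inputs with known planted structure.

Every downstream stage of the analysis is testable against ground truth:
planted drug->lncRNA log2 fold-change effects with replicate instances,
annotation sharing enriched among lncRNA-connected drug pairs, mRNAs linearly
co-expressed with chosen lncRNAs, and lncRNAs expressed predominantly in one
tissue.  Expression is simulated directly on the log2 scale (RMA-like), so a
fold change is a subtraction of a control from a treatment profile.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pharmacology import DrugAnnotation

# Per-operation offsets so each stage can be regenerated independently from
# the same config seed.
_RNG_OFFSETS = {
    "instances": 101,
    "annotations": 202,
    "tissue": 303,
    "coexpression": 404,
}

# Annotation vocabularies: (vocabulary size, per-item baseline probability).
# Sizes chosen so a drug carries a handful of indications/targets and a few
# dozen recorded side effects, loosely mirroring curated drug resources.
ANNOTATION_VOCABS = {
    "indications": (100, 0.03),
    "targets": (150, 0.02),
    "side_effects": (200, 0.10),
}
FINGERPRINT_LENGTH = 256
FINGERPRINT_ON_PROB = 0.10

# ATC level-1 classes; 13 classes as used for drug classification here.
ATC_CLASSES = ("A", "B", "C", "D", "G", "H", "J", "L", "M", "N", "P", "R", "S")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    All expression values are on the log2 scale.  ``noise_sd`` is the
    standard deviation of the per-instance log2-fold-change error (see
    :func:`generate_instances`).  ``edge_density`` is the fraction of
    drug-lncRNA pairs with a planted effect; ``annotation_enrichment`` is the
    multiplier applied to the per-item annotation-sharing probability of
    lncRNA-connected drug pairs.
    """

    n_drugs: int = 60
    n_lncrnas: int = 40
    n_mrnas: int = 500
    n_instances_per_drug: int = 3
    effect_log2fc: float = 2.5
    noise_sd: float = 0.3
    edge_density: float = 0.2
    annotation_enrichment: float = 5.0
    n_tissues: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_lncrnas", "n_mrnas", "n_instances_per_drug", "n_tissues"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("effect_log2fc", "noise_sd", "edge_density", "annotation_enrichment"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must be in [0, 1]")
        if self.annotation_enrichment < 1.0:
            raise ValueError("annotation_enrichment must be >= 1")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    def drug_ids(self) -> list[str]:
        return [f"drug_{i:03d}" for i in range(self.n_drugs)]

    def lncrna_ids(self) -> list[str]:
        return [f"lnc_{i:03d}" for i in range(self.n_lncrnas)]

    def mrna_ids(self) -> list[str]:
        return [f"mrna_{i:04d}" for i in range(self.n_mrnas)]

    def tissue_ids(self) -> list[str]:
        return [f"tissue_{i:02d}" for i in range(self.n_tissues)]


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator.

    ``effects``: (drug_id, lncrna_id, sign) triples, sign in {"up", "down"};
    no duplicate (drug, lncRNA) pairs.  ``tissue_assignments`` maps planted
    tissue-specific lncRNAs to their tissue.  ``coexpression_links`` holds
    (lncrna_id, mrna_id, sign) with sign the expected correlation sign.
    ``enriched_gene_sets`` names the gene sets composed predominantly of
    linked mRNAs.
    """

    effects: set[tuple[str, str, str]] = field(default_factory=set)
    tissue_assignments: dict[str, str] = field(default_factory=dict)
    coexpression_links: set[tuple[str, str, str]] = field(default_factory=set)
    enriched_gene_sets: set[str] = field(default_factory=set)

    def effect_pairs(self) -> set[tuple[str, str]]:
        return {(d, l) for d, l, _ in self.effects}

    def connected_drug_pairs(self) -> set[tuple[str, str]]:
        """Unordered drug pairs sharing at least one planted lncRNA."""
        by_lnc: dict[str, set[str]] = {}
        for d, l, _ in self.effects:
            by_lnc.setdefault(l, set()).add(d)
        pairs: set[tuple[str, str]] = set()
        for drugs in by_lnc.values():
            for a, b in itertools.combinations(sorted(drugs), 2):
                pairs.add((a, b))
        return pairs


def _rng(config: SynthConfig, op: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _RNG_OFFSETS[op]]))


def plant_effects(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[PlantedTruth, np.ndarray]:
    """Plant signed drug->lncRNA effects.

    Returns the truth plus the drugs x lncRNAs signed effect matrix (0 or
    +-effect_log2fc).  Uses the same stream as :func:`generate_instances`,
    so the planted truth matches the generated expression instances.
    """
    if rng is None:
        rng = _rng(config, "instances")
    drugs, lncs = config.drug_ids(), config.lncrna_ids()
    n_l = len(lncs)
    planted = rng.random((config.n_drugs, n_l)) < config.edge_density
    signs = np.where(rng.random((config.n_drugs, n_l)) < 0.5, 1.0, -1.0)
    effect = np.where(planted, signs * config.effect_log2fc, 0.0)
    truth = PlantedTruth()
    for i, d in enumerate(drugs):
        for j, l in enumerate(lncs):
            if planted[i, j]:
                truth.effects.add((d, l, "up" if signs[i, j] > 0 else "down"))
    return truth, effect


def generate_instances(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate treatment/control lncRNA expression instances.

    For each drug, ``n_instances_per_drug`` paired treatment/control profiles
    are produced.  The control is a per-lncRNA baseline plus measurement
    noise; the treatment is the instance's own control plus the planted
    effect (+-effect_log2fc for planted pairs, 0 otherwise) plus independent
    noise, so treatment - control has expectation equal to the planted effect
    and standard deviation ``noise_sd``.

    Returns (expression matrix lncRNAs x samples, instance manifest,
    PlantedTruth with ``effects`` filled).
    """
    rng = _rng(config, "instances")
    drugs, lncs = config.drug_ids(), config.lncrna_ids()
    n_l = len(lncs)
    truth, effect = plant_effects(config, rng)
    # baselines on a dyadic grid so zero-noise fold changes subtract exactly
    baseline = np.rint(rng.uniform(4.0, 10.0, size=n_l) * 65536.0) / 65536.0

    columns: dict[str, np.ndarray] = {}
    manifest_rows = []
    for i, d in enumerate(drugs):
        for k in range(config.n_instances_per_drug):
            inst = f"{d}_inst{k}"
            c_name, t_name = f"{inst}_ctl", f"{inst}_trt"
            control = baseline + rng.normal(0.0, config.noise_sd, n_l) if config.noise_sd > 0 else baseline.copy()
            fc_noise = rng.normal(0.0, config.noise_sd, n_l) if config.noise_sd > 0 else np.zeros(n_l)
            treatment = control + effect[i] + fc_noise
            columns[c_name] = control
            columns[t_name] = treatment
            manifest_rows.append(
                {"instance_id": inst, "drug_id": d, "treatment_sample": t_name, "control_sample": c_name}
            )

    expr = pd.DataFrame(columns, index=pd.Index(lncs, name="feature_id"))
    manifest = pd.DataFrame(manifest_rows)
    return expr, manifest, truth


def _injection_prob(enrichment: float, p_item: float) -> float:
    """Pair-level shared-item injection probability.

    Chosen so the sharing probability of a connected pair for one item is
    min(1, enrichment * p_item^2): base sharing p^2 plus injection q on the
    remaining mass, q = (min(1, e p^2) - p^2) / (1 - p^2).
    """
    target = min(1.0, enrichment * p_item * p_item)
    base = p_item * p_item
    if base >= 1.0:
        return 0.0
    return max(0.0, (target - base) / (1.0 - base))


def generate_drug_annotations(
    config: SynthConfig, truth: PlantedTruth
) -> dict[str, DrugAnnotation]:
    """Draw ATC class, annotation sets, and fingerprints per drug.

    Items are drawn independently per drug from finite integer-labelled
    vocabularies; for every drug pair sharing >=1 planted lncRNA an extra
    shared-item injection raises the pairwise sharing probability by the
    configured enrichment (capped at 1).  At enrichment 1 no injection
    occurs and drugs are annotated independently.
    """
    rng = _rng(config, "annotations")
    drugs = config.drug_ids()
    idx = {d: i for i, d in enumerate(drugs)}
    connected = sorted(truth.connected_drug_pairs())

    field_items: dict[str, np.ndarray] = {}
    specs = dict(ANNOTATION_VOCABS)
    specs["fingerprint"] = (FINGERPRINT_LENGTH, FINGERPRINT_ON_PROB)
    for fname, (vocab, p_item) in specs.items():
        has = rng.random((config.n_drugs, vocab)) < p_item
        q = _injection_prob(config.annotation_enrichment, p_item)
        if q > 0.0:
            for a, b in connected:
                inject = rng.random(vocab) < q
                has[idx[a]] |= inject
                has[idx[b]] |= inject
        field_items[fname] = has

    atc = rng.choice(ATC_CLASSES, size=config.n_drugs)

    annotations: dict[str, DrugAnnotation] = {}
    for i, d in enumerate(drugs):
        annotations[d] = DrugAnnotation(
            drug_id=d,
            atc_class=str(atc[i]),
            indications=frozenset(
                f"indication_{k}" for k in np.flatnonzero(field_items["indications"][i])
            ),
            targets=frozenset(f"target_{k}" for k in np.flatnonzero(field_items["targets"][i])),
            side_effects=frozenset(
                f"side_effect_{k}" for k in np.flatnonzero(field_items["side_effects"][i])
            ),
            fingerprint=field_items["fingerprint"][i].astype(np.uint8),
        )
    return annotations


def generate_tissue_panel(
    config: SynthConfig, truth: PlantedTruth, purity: float = 1.0
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulate a lncRNA x tissue expression panel plus anatomical classes.

    Half of the lncRNAs are planted tissue-specific: a fraction ``purity`` of
    their total expression falls in one assigned tissue (recorded in
    ``truth.tissue_assignments``), the remainder spread evenly.  The other
    lncRNAs are near-uniform across tissues.  Tissues are partitioned
    round-robin into anatomical classes.
    """
    if config.n_tissues < 2:
        raise ValueError("n_tissues must be >= 2 for a tissue panel")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    rng = _rng(config, "tissue")
    tissues = config.tissue_ids()
    lncs = config.lncrna_ids()
    n_t = len(tissues)

    n_classes = max(2, min(11, n_t // 2))
    tissue_class = {t: f"anat_{i % n_classes}" for i, t in enumerate(tissues)}

    n_specific = len(lncs) // 2
    specific = list(rng.choice(len(lncs), size=n_specific, replace=False))
    assigned_tissue = rng.integers(0, n_t, size=n_specific)

    truth.tissue_assignments.clear()
    rows = np.empty((len(lncs), n_t))
    spec_pos = {int(j): int(t) for j, t in zip(specific, assigned_tissue)}
    for i in range(len(lncs)):
        total = rng.uniform(50.0, 150.0)
        if i in spec_pos:
            t = spec_pos[i]
            p = np.full(n_t, (1.0 - purity) / (n_t - 1))
            p[t] = purity
            truth.tissue_assignments[lncs[i]] = tissues[t]
        else:
            # near-uniform: tight Dirichlet around the uniform distribution
            p = rng.dirichlet(np.full(n_t, 200.0))
        rows[i] = total * p

    panel = pd.DataFrame(rows, index=pd.Index(lncs, name="lncrna_id"), columns=tissues)
    return panel, tissue_class


# Gene-set layout for the co-expression stage.
N_COEX_LNCRNAS = 5
MRNAS_PER_LNCRNA = 10
N_RANDOM_SETS = 20
GENE_SET_SIZE = 15
# mRNAs not linked to any lncRNA get their own biological variation so null
# correlations are well defined even at noise_sd = 0.
UNLINKED_MRNA_SD = 0.5


def generate_coexpression(
    config: SynthConfig,
    truth: PlantedTruth,
    lnc_expr: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Simulate mRNA profiles co-expressed with chosen lncRNAs plus GMT sets.

    Linked mRNAs are the lncRNA profile (sign-flipped for negative links)
    plus a baseline shift and Gaussian noise with sd ``noise_sd``, so at zero
    noise the Pearson correlation is exactly +-1.  One enriched gene set per
    linked lncRNA contains all of its linked mRNAs plus a few random genes;
    additional random sets serve as the null background.  Fills
    ``truth.coexpression_links`` and ``truth.enriched_gene_sets``.
    """
    rng = _rng(config, "coexpression")
    mrnas = config.mrna_ids()
    samples = lnc_expr.columns
    n_s = len(samples)

    # lncRNAs eligible for links: need expression variance (>=1 planted drug)
    drugged = {l for _, l, _ in truth.effects}
    eligible = [l for l in lnc_expr.index if l in drugged]
    chosen = eligible[: min(N_COEX_LNCRNAS, len(eligible))]

    truth.coexpression_links.clear()
    truth.enriched_gene_sets.clear()

    mat = np.empty((len(mrnas), n_s))
    linked: dict[str, list[str]] = {l: [] for l in chosen}
    next_mrna = 0
    for l in chosen:
        profile = lnc_expr.loc[l].to_numpy()
        for _ in range(min(MRNAS_PER_LNCRNA, len(mrnas) - next_mrna)):
            m = mrnas[next_mrna]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            noise = rng.normal(0.0, config.noise_sd, n_s) if config.noise_sd > 0 else 0.0
            mat[next_mrna] = sign * profile + rng.uniform(2.0, 8.0) + noise
            truth.coexpression_links.add((l, m, "up" if sign > 0 else "down"))
            linked[l].append(m)
            next_mrna += 1
    for i in range(next_mrna, len(mrnas)):
        mat[i] = rng.uniform(4.0, 10.0) + rng.normal(0.0, UNLINKED_MRNA_SD, n_s)

    mrna_expr = pd.DataFrame(mat, index=pd.Index(mrnas, name="feature_id"), columns=samples)

    gene_sets: dict[str, list[str]] = {}
    for l, members in linked.items():
        pad = [m for m in rng.choice(mrnas, size=GENE_SET_SIZE, replace=False) if m not in members]
        name = f"set_enriched_{l}"
        gene_sets[name] = sorted(set(members) | set(pad[: GENE_SET_SIZE - len(members)]))
        truth.enriched_gene_sets.add(name)
    for k in range(N_RANDOM_SETS):
        gene_sets[f"set_random_{k:02d}"] = sorted(
            rng.choice(mrnas, size=GENE_SET_SIZE, replace=False)
        )
    return mrna_expr, gene_sets
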