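"""Synthetic paired miRNA/mRNA cohorts with planted ground truth.

The generator emulates the study design the pipeline targets: two small
patient groups (a volume-overload and an ischemic cardiomyopathy arm,
labelled VCM and ICM), negative-binomial sequencing counts, a subset of
features with planted log2 effects above the differential-expression
threshold, and planted miRNA->target couplings that induce strong negative
cross-sample correlation.

Counts follow NB(mu, alpha) in the mean-dispersion parameterization
Var = mu + alpha * mu^2. Library sizes are log-uniform over a configured
interval. A repressive coupling is applied at the log-mean level: the
target gene's log2 mean is shifted by ``coupling_strength`` times the
miRNA's per-sample log2 deviation (group effect plus a latent per-sample
term), so differential expression and correlation structure arise from a
single mechanism rather than post-hoc injection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneSetCollection,
    TargetEvidenceTable,
    EVIDENCE_COLUMNS,
    PREDICTION_DATABASES,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_paired_counts",
    "generate_evidence_fixture",
    "generate_gene_sets",
    "generate_clinical_table",
    "generate_ct_table",
    "generate_luciferase",
]


@dataclass
class SimConfig:
    """Parameters of a synthetic paired cohort.

    Defaults mirror the paired design the pipeline targets: 4 + 3 samples,
    planted effects of |log2FC| in [2.0, 2.5] (well above the 0.5 screen
    threshold), NB dispersion 0.05, and repressive couplings with slope
    -1.5 on the log2 scale.
    """

    n_group_a: int = 4
    n_group_b: int = 3
    n_genes: int = 2000
    n_mirnas: int = 200
    n_de_genes: int = 60
    n_de_mirnas: int = 5
    lfc_range: tuple[float, float] = (2.0, 2.5)
    dispersion: float = 0.05
    lib_size_range: tuple[float, float] = (8e5, 1.2e6)
    n_repressive_pairs: int = 4
    coupling_strength: float = -1.5
    latent_sd: float = 0.4  # per-sample log2 SD of coupled miRNAs beyond the group effect
    seed: int = 0
    group_labels: tuple[str, str] = ("VCM", "ICM")

    def validate(self) -> None:
        for name in ("n_group_a", "n_group_b", "n_genes", "n_mirnas"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not (0 <= self.n_de_genes <= self.n_genes):
            raise ValueError("n_de_genes must lie in [0, n_genes]")
        if not (0 <= self.n_de_mirnas <= self.n_mirnas):
            raise ValueError("n_de_mirnas must lie in [0, n_mirnas]")
        if self.n_repressive_pairs > self.n_de_mirnas * self.n_de_genes:
            raise ValueError("n_repressive_pairs exceeds n_de_mirnas * n_de_genes")
        if self.n_repressive_pairs > self.n_de_genes:
            raise ValueError(
                "n_repressive_pairs exceeds n_de_genes (each coupled target is distinct)"
            )
        if self.n_repressive_pairs > 0 and self.coupling_strength >= 0:
            raise ValueError("coupling_strength must be < 0 for repressive pairs")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.lfc_range[0] < 0 or self.lfc_range[1] < self.lfc_range[0]:
            raise ValueError("lfc_range must be a non-negative increasing interval")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[1] < self.lib_size_range[0]:
            raise ValueError("lib_size_range must be a positive increasing interval")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the matrices."""

    de_genes: dict[str, float] = field(default_factory=dict)
    de_mirnas: dict[str, float] = field(default_factory=dict)
    repressive_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    decoy_pairs: list[tuple[str, str]] = field(default_factory=list)

    def validate(self, gene_ids=None, mirna_ids=None) -> None:
        planted = {(m, g) for m, g, _ in self.repressive_pairs}
        if planted & set(self.decoy_pairs):
            raise ValueError("repressive and decoy pairs overlap")
        if gene_ids is not None:
            genes = set(gene_ids)
            for gid in self.de_genes:
                if gid not in genes:
                    raise ValueError(f"truth gene {gid!r} absent from matrix")
        if mirna_ids is not None:
            mirnas = set(mirna_ids)
            for mid in self.de_mirnas:
                if mid not in mirnas:
                    raise ValueError(f"truth miRNA {mid!r} absent from matrix")

    def to_json(self, path) -> None:
        payload = {
            "de_genes": self.de_genes,
            "de_mirnas": self.de_mirnas,
            "repressive_pairs": [list(p) for p in self.repressive_pairs],
            "decoy_pairs": [list(p) for p in self.decoy_pairs],
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha mu^2; Poisson limit for alpha ~ 0."""
    mu = np.maximum(mu, 1e-12)
    if alpha < 1e-9:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_paired_counts(
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, SimTruth]:
    """Draw paired mRNA and miRNA count matrices over one shared sample set.

    Returns (mRNA counts, miRNA counts, sample metadata, planted truth).
    Identical seeds give byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_a, n_b = config.n_group_a, config.n_group_b
    n_samples = n_a + n_b
    label_a, label_b = config.group_labels
    sample_ids = [f"{label_a}{i + 1}" for i in range(n_a)] + [
        f"{label_b}{i + 1}" for i in range(n_b)
    ]
    meta = pd.DataFrame(
        {"sample_id": sample_ids, "group": [label_a] * n_a + [label_b] * n_b}
    )
    # +1/2 in group A, -1/2 in group B: effect = log2(mean_A / mean_B)
    half_effect_sign = np.array([0.5] * n_a + [-0.5] * n_b)

    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    mirna_ids = [f"mir-{i + 1:04d}" for i in range(config.n_mirnas)]

    truth = SimTruth()

    def _plant_effects(ids: list[str], n_de: int) -> tuple[dict[str, float], np.ndarray]:
        chosen = rng.choice(len(ids), size=n_de, replace=False)
        magnitudes = rng.uniform(*config.lfc_range, size=n_de)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        effects = np.zeros(len(ids))
        effects[chosen] = magnitudes * signs
        return {ids[i]: float(effects[i]) for i in chosen}, effects

    truth.de_genes, gene_effects = _plant_effects(gene_ids, config.n_de_genes)
    truth.de_mirnas, mirna_effects = _plant_effects(mirna_ids, config.n_de_mirnas)

    # log2 per-sample deviation of each feature from its baseline
    gene_dev = np.outer(gene_effects, half_effect_sign)
    mirna_dev = np.outer(mirna_effects, half_effect_sign)

    # repressive couplings: pick DE miRNAs round-robin, DE genes without reuse
    if config.n_repressive_pairs > 0:
        de_mirna_idx = [mirna_ids.index(m) for m in truth.de_mirnas]
        de_gene_idx = [gene_ids.index(g) for g in truth.de_genes]
        target_idx = rng.choice(
            de_gene_idx, size=config.n_repressive_pairs, replace=False
        )
        latent_given: set[int] = set()
        for k, g_idx in enumerate(target_idx):
            m_idx = de_mirna_idx[k % len(de_mirna_idx)]
            if m_idx not in latent_given:
                mirna_dev[m_idx] += rng.normal(0.0, config.latent_sd, size=n_samples)
                latent_given.add(m_idx)
            gene_dev[g_idx] = config.coupling_strength * mirna_dev[m_idx]
            induced = config.coupling_strength * mirna_effects[m_idx]
            truth.de_genes[gene_ids[g_idx]] = float(induced)
            truth.repressive_pairs.append(
                (mirna_ids[m_idx], gene_ids[g_idx], float(config.coupling_strength))
            )

    def _draw_matrix(ids: list[str], dev: np.ndarray) -> CountMatrix:
        n_feat = len(ids)
        # relative abundances: log-normal over ~4 orders of magnitude
        rel = 2.0 ** rng.normal(0.0, 2.0, size=n_feat)
        rel /= rel.sum()
        libs = np.exp(
            rng.uniform(np.log(config.lib_size_range[0]), np.log(config.lib_size_range[1]),
                        size=n_samples)
        )
        mu = rel[:, None] * libs[None, :] * (2.0 ** dev)
        counts = _nb_draw(rng, mu, config.dispersion)
        return CountMatrix(ids, sample_ids, counts)

    mrna = _draw_matrix(gene_ids, gene_dev)
    mirna = _draw_matrix(mirna_ids, mirna_dev)
    truth.validate(gene_ids, mirna_ids)
    return mrna, mirna, meta, truth


def generate_evidence_fixture(
    truth: SimTruth,
    n_decoys: int,
    seed: int,
    gene_ids: list[str] | None = None,
    mirna_ids: list[str] | None = None,
    de_decoy_fraction: float = 0.05,
) -> TargetEvidenceTable:
    """Evidence table containing every planted pair plus decoy rows.

    Every planted repressive pair appears in at least one database row
    (validated or predicted at random). Decoy rows are pairs that are in
    the table but not coupled: most reference miRNAs outside the DE panel
    (as real target databases are dominated by rows irrelevant to any
    given contrast), and a small fraction pair a DE miRNA with an
    uncoupled gene so the correlation gate is exercised non-circularly.
    Decoys are recorded on ``truth.decoy_pairs``.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    if not truth.de_mirnas and not truth.repressive_pairs:
        raise ValueError("truth is empty: nothing to put in the evidence table")
    rng = np.random.default_rng(seed)
    prediction_dbs = sorted(PREDICTION_DATABASES)

    rows: list[dict] = []

    def _row(mirna: str, gene: str, validated: bool) -> dict:
        if validated:
            db = rng.choice(["mirtarbase", "tarbase"])
            return dict.fromkeys(EVIDENCE_COLUMNS) | {
                "database": db,
                "mirna_acc": f"ACC:{mirna}",
                "mirna_id": mirna,
                "target_symbol": gene,
                "type": "validated",
                "pubmed": str(rng.integers(10000000, 40000000)),
            }
        db = rng.choice(prediction_dbs)
        return dict.fromkeys(EVIDENCE_COLUMNS) | {
            "database": db,
            "mirna_acc": f"ACC:{mirna}",
            "mirna_id": mirna,
            "target_symbol": gene,
            "type": "predicted",
            "score": float(np.round(rng.uniform(0.5, 1.0), 3)),
        }

    planted = {(m, g) for m, g, _ in truth.repressive_pairs}
    for mirna, gene, _ in truth.repressive_pairs:
        rows.append(_row(mirna, gene, validated=bool(rng.random() < 0.5)))

    coupled_genes = {g for _, g, _ in truth.repressive_pairs}
    de_mirnas = sorted(truth.de_mirnas)
    if mirna_ids is None:
        mirna_ids = de_mirnas + [f"decoy-mir-{i + 1:04d}" for i in range(max(n_decoys, 1))]
    if gene_ids is None:
        gene_ids = sorted(truth.de_genes) + [
            f"DECOYG{i + 1:05d}" for i in range(max(n_decoys, 1))
        ]
    non_de_mirnas = [m for m in mirna_ids if m not in truth.de_mirnas]
    # genes eligible for DE-miRNA decoys: uncoupled and not planted DE
    null_genes = [g for g in gene_ids if g not in coupled_genes and g not in truth.de_genes]

    n_de_decoys = int(round(n_decoys * de_decoy_fraction))
    decoys: list[tuple[str, str]] = []
    attempts = 0
    while len(decoys) < n_decoys and attempts < 50 * (n_decoys + 1):
        attempts += 1
        if len(decoys) < n_de_decoys and de_mirnas and null_genes:
            pair = (
                de_mirnas[int(rng.integers(len(de_mirnas)))],
                null_genes[int(rng.integers(len(null_genes)))],
            )
        else:
            pair = (
                non_de_mirnas[int(rng.integers(len(non_de_mirnas)))],
                gene_ids[int(rng.integers(len(gene_ids)))],
            )
        if pair in planted or pair in decoys:
            continue
        decoys.append(pair)
    for mirna, gene in decoys:
        rows.append(_row(mirna, gene, validated=bool(rng.random() < 0.3)))
    truth.decoy_pairs = decoys
    truth.validate()
    return TargetEvidenceTable(pd.DataFrame(rows, columns=EVIDENCE_COLUMNS))


def generate_gene_sets(
    gene_ids: list[str],
    truth: SimTruth | None = None,
    n_sets: int = 10,
    set_size: int = 20,
    seed: int = 0,
    namespace: str = "KEGG",
) -> GeneSetCollection:
    """Random gene sets, plus (when truth is given) one set enriched for
    planted up-regulated genes and one for down-regulated genes."""
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        members = rng.choice(gene_ids, size=min(set_size, len(gene_ids)), replace=False)
        sets[f"random_set_{i + 1:02d}"] = [str(g) for g in members]
    if truth is not None and truth.de_genes:
        up = [g for g, e in truth.de_genes.items() if e > 0]
        down = [g for g, e in truth.de_genes.items() if e < 0]
        if up:
            sets["planted_up"] = up
        if down:
            sets["planted_down"] = down
    return GeneSetCollection(sets, namespace=namespace)


DEFAULT_CLINICAL_VARIABLES = [
    # (name, kind, group A params, group B params); continuous = (mean, sd)
    ("Age (years)", "continuous", (64.0, 11.0), (66.0, 8.0)),
    ("LVEF (%)", "continuous", (48.0, 11.0), (38.0, 16.0)),
    ("LVEDD (mm)", "continuous", (60.0, 5.0), (60.0, 2.0)),
    ("Medication A", "categorical", 0.8, 0.8),
    ("Medication B", "categorical", 0.25, 0.9),
]


def generate_clinical_table(
    config: SimConfig,
    seed: int,
    variables=DEFAULT_CLINICAL_VARIABLES,
) -> pd.DataFrame:
    """Per-sample clinical values: Gaussian continuous variables and
    Bernoulli categorical ones, in long form (variable, kind, sample, group,
    value)."""
    if config.n_group_a < 2 or config.n_group_b < 2:
        raise ValueError("clinical generation needs >= 2 samples per group")
    rng = np.random.default_rng(seed)
    label_a, label_b = config.group_labels
    rows = []
    for name, kind, pa, pb in variables:
        for label, n, params in (
            (label_a, config.n_group_a, pa),
            (label_b, config.n_group_b, pb),
        ):
            if kind == "continuous":
                mean, sd = params
                if sd <= 0:
                    raise ValueError(f"{name}: Gaussian draw needs sd > 0")
                values = rng.normal(mean, sd, size=n)
            else:
                values = rng.random(size=n) < params
            for i, v in enumerate(values):
                rows.append(
                    {
                        "variable": name,
                        "kind": kind,
                        "sample_id": f"{label}{i + 1}",
                        "group": label,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)


def generate_ct_table(
    config: SimConfig,
    seed: int,
    targets: dict[str, float] | None = None,
    references: tuple[str, ...] = ("GAPDH", "ACTB"),
    base_ct: float = 20.0,
    noise_sd: float = 0.15,
) -> pd.DataFrame:
    """qPCR Ct table with >= 2 reference assays per sample.

    ``targets`` maps assay name to the planted log2 expression difference of
    group A over group B; a positive value lowers group A's Ct (one cycle
    per doubling). Per-sample loading offsets are shared by every assay of
    the sample, so ddCt normalization cancels them.
    """
    if targets is None:
        targets = {"TARGET1": 1.0}
    if config.n_group_a < 2 or config.n_group_b < 2:
        raise ValueError("Ct generation needs >= 2 samples per group")
    rng = np.random.default_rng(seed)
    label_a, label_b = config.group_labels
    rows = []
    for label, n, sign in ((label_a, config.n_group_a, +0.5), (label_b, config.n_group_b, -0.5)):
        for i in range(n):
            sample = f"{label}{i + 1}"
            loading = rng.normal(0.0, 0.5)
            for ref in references:
                rows.append(
                    {
                        "sample_id": sample,
                        "group": label,
                        "assay_id": ref,
                        "role": "reference",
                        "ct": base_ct + loading + rng.normal(0.0, noise_sd),
                    }
                )
            for assay, lfc in targets.items():
                rows.append(
                    {
                        "sample_id": sample,
                        "group": label,
                        "assay_id": assay,
                        "role": "target",
                        # higher expression -> lower Ct
                        "ct": base_ct + 4.0 + loading - sign * lfc + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


def generate_luciferase(
    config: SimConfig,
    seed: int,
    knockdown: dict[str, float] | None = None,
    n_replicates: int = 3,
    cv: float = 0.05,
) -> pd.DataFrame:
    """Dual-luciferase readings: paired experimental/control luminescence in
    triplicate per condition.

    ``knockdown`` maps condition name to the fractional activity reduction
    relative to the baseline (0 = no repression). Default mirrors a
    wild-type 3'UTR repressed 40% by its cognate mimic and a seed-mutant
    construct left untouched.
    """
    if knockdown is None:
        knockdown = {"NC": 0.0, "WT+mimic": 0.4, "Mut+mimic": 0.0}
    if n_replicates < 3:
        raise ValueError("luciferase sets need >= 3 replicates per condition")
    rng = np.random.default_rng(seed)
    rows = []
    for condition, kd in knockdown.items():
        if not (0 <= kd < 1):
            raise ValueError(f"{condition}: knockdown must lie in [0, 1)")
        for rep in range(n_replicates):
            control = rng.lognormal(mean=np.log(1e5), sigma=0.2)
            activity = (1.0 - kd) * (1.0 + rng.normal(0.0, cv))
            rows.append(
                {
                    "condition": condition,
                    "replicate": rep + 1,
                    "signal": control * activity,
                    "control": control,
                }
            )
    return pd.DataFrame(rows)
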