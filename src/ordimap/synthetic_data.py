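"""Study-shaped synthetic miRNA+mRNA expression data with ground truth.

The generator emulates the design of a diseased-vs-control liver
co-expression study: 13 diseased samples with an ordinal necrosis grade
and 17 controls, ~109 miRNAs and ~531 mRNAs.  Necrosis acts as a
confounder — hepatocyte genes fall and infiltrate genes rise with the
grade — on top of block-structured functional co-expression and planted
miRNA–mRNA couplings of both kinds seen in real data: inhibitory
(miRNA up ⇒ target down, negative correlation) and feed-forward (a shared
transcription-factor latent drives both up, positive correlation).

On the log2 scale, a diseased sample j with necrosis grade g_j gives gene
i the value

    baseline_i + dir_i · covariate_effect · g_j
             + block_effect_sd · f_{b(i), j}
             + Σ_couplings ± coupling · u_{pair, j}
             + Normal(0, noise_sd)

with dir_i ∈ {−1 hepatocyte, +1 infiltrate, 0 neutral}; control samples
have no covariate term.  All randomness flows from one integer seed
through a single numpy Generator (PCG64), so identical configurations
yield bit-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix_io import (
    MIRNA,
    MRNA,
    ExpressionMatrix,
    GeneAnnotationTable,
    SampleTable,
    SeedTable,
    TargetTable,
)

#: the study's nine liver functional classes
FUNCTIONAL_CLASSES = (
    "CYP450",
    "transcription_factors",
    "complement",
    "proliferation",
    "HLA_class_II",
    "monocytes_macrophages",
    "T_cells",
    "T_NK_cells",
    "B_cells",
)

HEPATOCYTE = "hepatocyte"
INFILTRATE = "infiltrate"
NEUTRAL = "neutral"

_DIRECTION_SIGN = {HEPATOCYTE: -1.0, INFILTRATE: 1.0, NEUTRAL: 0.0}


class ConfigError(ValueError):
    """Invalid StudyConfig field."""


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 109 miRNAs + 531 mRNAs over
    13 diseased and 17 control samples, nine functional blocks, an ordinal
    necrosis scale 1..4 assigned cyclically to diseased samples.
    """

    n_mirna: int = 109
    n_mrna: int = 531
    n_case_samples: int = 13
    n_control_samples: int = 17
    n_functional_blocks: int = 9
    frac_hepatocyte_genes: float = 0.45
    necrosis_grades: tuple = (1, 2, 3, 4)
    covariate_effect: float = 1.2
    block_effect_sd: float = 0.8
    inhibitory_coupling: float = 1.0
    feedforward_coupling: float = 1.0
    noise_sd: float = 0.5
    n_target_pairs: int = 100
    n_shared_seed_groups: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_mirna",
            "n_mrna",
            "n_case_samples",
            "n_control_samples",
            "n_functional_blocks",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1 (got {getattr(self, name)})")
        if not 0 <= self.frac_hepatocyte_genes <= 1:
            raise ConfigError("frac_hepatocyte_genes must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        for name in ("covariate_effect", "block_effect_sd", "inhibitory_coupling", "feedforward_coupling"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not self.necrosis_grades:
            raise ConfigError("necrosis_grades must be nonempty")
        if self.n_target_pairs < 0 or self.n_target_pairs > self.n_mirna * self.n_mrna:
            raise ConfigError("n_target_pairs must lie in [0, n_mirna * n_mrna]")
        if self.n_shared_seed_groups < 0 or 2 * self.n_shared_seed_groups > self.n_mirna:
            raise ConfigError("n_shared_seed_groups needs 2 miRNAs per group")

    @property
    def n_genes(self) -> int:
        return self.n_mirna + self.n_mrna


@dataclass
class GroundTruth:
    """Planted structure of a synthetic bundle."""

    gene_direction: pd.Series          # gene -> hepatocyte|infiltrate|neutral
    block_membership: pd.Series        # gene -> block id (-1 = none)
    coupled_pairs: list[tuple[str, str, int]]   # (miRNA, mRNA, sign)
    baseline_expression: pd.Series     # gene -> log2 value at zero necrosis


@dataclass
class StudyBundle:
    """A complete synthetic study: matrices, metadata tables and truth."""

    case_matrix: ExpressionMatrix
    control_matrix: ExpressionMatrix
    samples: SampleTable
    annotations: GeneAnnotationTable
    targets: TargetTable
    seeds: SeedTable
    truth: GroundTruth
    config: StudyConfig

    def __post_init__(self) -> None:
        if self.case_matrix.gene_ids != self.control_matrix.gene_ids:
            raise ConfigError("case and control matrices must share gene ids")
        genes = set(self.case_matrix.gene_ids)
        for m, t in self.targets.pairs():
            if m not in genes or t not in genes:
                raise ConfigError(f"target pair ({m}, {t}) not in the matrices")

    def necrosis_covariate(self) -> np.ndarray:
        return self.samples.necrosis(self.case_matrix.sample_ids)


def _assign_directions(config: StudyConfig, rng: np.random.Generator) -> np.ndarray:
    """Fixed-proportion direction labels, shuffled.

    ``frac_hepatocyte_genes`` of genes are hepatocyte; an equal share is
    infiltrate; the remainder (if any) is neutral.  The analysed genes of
    the emulated study are differentially expressed by construction, so
    nearly all carry a necrosis direction.
    """
    n = config.n_genes
    n_hep = int(round(config.frac_hepatocyte_genes * n))
    n_inf = min(n_hep, n - n_hep)
    labels = np.array(
        [HEPATOCYTE] * n_hep + [INFILTRATE] * n_inf + [NEUTRAL] * (n - n_hep - n_inf),
        dtype=object,
    )
    rng.shuffle(labels)
    return labels


def _random_seed_sequences(config: StudyConfig, rng: np.random.Generator) -> list[str]:
    """7-base seeds over {A,C,G,U}; the first n_shared_seed_groups pairs of
    miRNAs share a seed, the rest are unique."""
    bases = np.array(list("ACGU"))
    taken: set[str] = set()

    def fresh() -> str:
        while True:
            s = "".join(rng.choice(bases, size=7))
            if s not in taken:
                taken.add(s)
                return s

    seeds: list[str] = []
    for _ in range(config.n_shared_seed_groups):
        s = fresh()
        seeds.extend([s, s])
    while len(seeds) < config.n_mirna:
        seeds.append(fresh())
    return seeds[: config.n_mirna]


def generate_study(config: StudyConfig) -> StudyBundle:
    """Generate a study-shaped bundle with full ground truth.

    Deterministic: identical config (including ``rng_seed``) gives a
    bit-identical bundle.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_mir, n_mrna = config.n_mirna, config.n_mrna
    n_genes = config.n_genes

    mirna_ids = [f"miR-{i + 1:04d}" for i in range(n_mir)]
    mrna_ids = [f"gene-{i + 1:04d}" for i in range(n_mrna)]
    gene_ids = mirna_ids + mrna_ids
    species = pd.Series([MIRNA] * n_mir + [MRNA] * n_mrna, index=gene_ids)

    case_ids = [f"ALF{j + 1:02d}" for j in range(config.n_case_samples)]
    ctrl_ids = [f"CTRL{j + 1:02d}" for j in range(config.n_control_samples)]
    grades = np.array(
        [config.necrosis_grades[j % len(config.necrosis_grades)] for j in range(config.n_case_samples)],
        dtype=float,
    )

    baseline = rng.normal(8.0, 3.0, size=n_genes)
    directions = _assign_directions(config, rng)
    dir_sign = np.array([_DIRECTION_SIGN[d] for d in directions])

    # functional blocks: mRNAs only, cyclic assignment then shuffled
    blocks = np.full(n_genes, -1, dtype=int)
    mrna_blocks = np.arange(n_mrna) % config.n_functional_blocks
    rng.shuffle(mrna_blocks)
    blocks[n_mir:] = mrna_blocks

    # per-condition latent block factors (biological co-expression, present
    # in both conditions)
    f_case = rng.standard_normal((config.n_functional_blocks, config.n_case_samples))
    f_ctrl = rng.standard_normal((config.n_functional_blocks, config.n_control_samples))

    case = np.tile(baseline[:, None], (1, config.n_case_samples))
    ctrl = np.tile(baseline[:, None], (1, config.n_control_samples))
    case += dir_sign[:, None] * config.covariate_effect * grades[None, :]
    has_block = blocks >= 0
    case[has_block] += config.block_effect_sd * f_case[blocks[has_block]]
    ctrl[has_block] += config.block_effect_sd * f_ctrl[blocks[has_block]]

    # planted miRNA–mRNA couplings
    pair_idx = rng.choice(n_mir * n_mrna, size=config.n_target_pairs, replace=False)
    pair_mir = pair_idx // n_mrna
    pair_mrna = pair_idx % n_mrna
    if config.inhibitory_coupling > 0 and config.feedforward_coupling > 0:
        pair_signs = np.where(np.arange(config.n_target_pairs) % 2 == 0, -1, 1)
    elif config.feedforward_coupling > 0 and config.inhibitory_coupling == 0:
        pair_signs = np.ones(config.n_target_pairs, dtype=int)
    elif config.inhibitory_coupling > 0 and config.feedforward_coupling == 0:
        pair_signs = -np.ones(config.n_target_pairs, dtype=int)
    else:
        pair_signs = np.where(np.arange(config.n_target_pairs) % 2 == 0, -1, 1)

    coupled_pairs: list[tuple[str, str, int]] = []
    for p in range(config.n_target_pairs):
        i_mir = int(pair_mir[p])
        i_mrna = n_mir + int(pair_mrna[p])
        sign = int(pair_signs[p])
        strength = config.inhibitory_coupling if sign < 0 else config.feedforward_coupling
        u_case = rng.standard_normal(config.n_case_samples)
        u_ctrl = rng.standard_normal(config.n_control_samples)
        case[i_mir] += strength * u_case
        ctrl[i_mir] += strength * u_ctrl
        case[i_mrna] += sign * strength * u_case
        ctrl[i_mrna] += sign * strength * u_ctrl
        coupled_pairs.append((mirna_ids[i_mir], mrna_ids[int(pair_mrna[p])], sign))

    case += rng.normal(0.0, config.noise_sd, size=case.shape)
    ctrl += rng.normal(0.0, config.noise_sd, size=ctrl.shape)

    case_matrix = ExpressionMatrix(pd.DataFrame(case, index=gene_ids, columns=case_ids), species)
    control_matrix = ExpressionMatrix(pd.DataFrame(ctrl, index=gene_ids, columns=ctrl_ids), species)

    samples = SampleTable(
        pd.DataFrame(
            {
                "condition": ["case"] * len(case_ids) + ["control"] * len(ctrl_ids),
                "necrosis": list(grades) + [np.nan] * len(ctrl_ids),
            },
            index=case_ids + ctrl_ids,
        )
    )

    class_names = [
        FUNCTIONAL_CLASSES[b % len(FUNCTIONAL_CLASSES)] if b >= 0 else None
        for b in blocks
    ]
    annotations = GeneAnnotationTable(
        pd.DataFrame(
            {
                "species": species.to_numpy(),
                "functional_class": class_names,
                "fold_change": np.nan,
            },
            index=gene_ids,
        )
    )

    targets = TargetTable(
        pd.DataFrame(
            {
                "mirna_id": [p[0] for p in coupled_pairs],
                "mrna_id": [p[1] for p in coupled_pairs],
                "mirsvr_score": rng.uniform(-2.0, -0.1, size=len(coupled_pairs)),
                "conserved": True,
            }
        )
    )

    seeds = SeedTable(
        pd.DataFrame({"mirna_id": mirna_ids, "seed_sequence": _random_seed_sequences(config, rng)})
    )

    truth = GroundTruth(
        gene_direction=pd.Series(directions, index=gene_ids),
        block_membership=pd.Series(blocks, index=gene_ids),
        coupled_pairs=coupled_pairs,
        baseline_expression=pd.Series(baseline, index=gene_ids),
    )

    return StudyBundle(
        case_matrix=case_matrix,
        control_matrix=control_matrix,
        samples=samples,
        annotations=annotations,
        targets=targets,
        seeds=seeds,
        truth=truth,
        config=config,
    )


def truth_report(bundle: StudyBundle) -> pd.DataFrame:
    """One row per gene with direction, block and coupling partners.

    Round-trips: :func:`truth_from_report` reconstructs the GroundTruth.
    """
    truth = bundle.truth
    partners: dict[str, list[str]] = {g: [] for g in truth.gene_direction.index}
    for mir, mrna, sign in truth.coupled_pairs:
        tag = f"{mrna}:{sign:+d}"
        partners[mir].append(tag)
        partners[mrna].append(f"{mir}:{sign:+d}")
    report = pd.DataFrame(
        {
            "direction": truth.gene_direction,
            "block": truth.block_membership,
            "baseline": truth.baseline_expression,
            "partners": [";".join(partners[g]) for g in truth.gene_direction.index],
        }
    )
    report.index.name = "gene_id"
    return report


def truth_from_report(report: pd.DataFrame, species: pd.Series) -> GroundTruth:
    """Reconstruct a GroundTruth from :func:`truth_report` output."""
    pairs: set[tuple[str, str, int]] = set()
    for gene, row in report.iterrows():
        val = row["partners"]
        if pd.isna(val) or val == "":
            continue
        for tag in str(val).split(";"):
            partner, sign = tag.rsplit(":", 1)
            if species.get(gene) == MIRNA:
                pairs.add((gene, partner, int(sign)))
            else:
                pairs.add((partner, gene, int(sign)))
    return GroundTruth(
        gene_direction=report["direction"],
        block_membership=report["block"].astype(int),
        coupled_pairs=sorted(pairs),
        baseline_expression=report["baseline"],
    )


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain TSV files; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "case_matrix": out / "case_matrix.tsv",
        "control_matrix": out / "control_matrix.tsv",
        "samples": out / "samples.tsv",
        "annotations": out / "annotations.tsv",
        "targets": out / "targets.tsv",
        "seeds": out / "seeds.tsv",
        "truth": out / "truth.tsv",
    }
    bundle.case_matrix.to_tsv(files["case_matrix"])
    bundle.control_matrix.to_tsv(files["control_matrix"])
    bundle.samples.to_tsv(files["samples"])
    bundle.annotations.to_tsv(files["annotations"])
    bundle.targets.to_tsv(files["targets"])
    bundle.seeds.to_tsv(files["seeds"])
    truth_report(bundle).to_csv(files["truth"], sep="\t")
    return files
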