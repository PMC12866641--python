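"""Seeded synthetic datasets shaped like the two showcase use cases.

Two generators produce validated long tables with no external downloads:

* :func:`make_pbmc_like` — a dice-mode table of gene dysregulation across
  PBMC populations and four age-sex conditions (YM/OM/YF/OF).  Presence of
  a (gene, cell type, condition) triple is Bernoulli(sparsity); one
  designated XIST-like gene is present in every cell type but only in the
  female conditions, emulating the canonical sex-specific signal, and the
  built plot keeps the ``top_k`` genes with the most dysregulated triples.

* :func:`make_zebra_like` — a domino-mode table of four neurodegeneration
  genes across brain cell types, five disease-vs-control contrasts and two
  sexes, with log2 fold-change stand-ins drawn from N(0, sigma) and
  -log10 p stand-ins from an exponential distribution.

Both are pure functions of their config: the same seed yields byte-
identical tables.  They emulate the *structure* of the real datasets
(axes, cardinalities, the sex-specific gene), not their measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import LongTable, VariableRoles, validate_table
from .errors import DegenerateConfig

PBMC_CELL_TYPES = (
    "B cells",
    "CD4 T cells",
    "CD8 T cells",
    "NK cells",
    "CD14 Monocytes",
    "CD16 Monocytes",
    "Dendritic cells",
    "Plasma cells",
)

AGE_SEX_CONDITIONS = ("YM", "OM", "YF", "OF")
FEMALE_CONDITIONS = ("YF", "OF")

BRAIN_CELL_TYPES = (
    "Excitatory neurons",
    "Inhibitory neurons",
    "Astrocytes",
    "Microglia",
    "Oligodendrocytes",
    "OPC",
)

DISEASE_CONTRASTS = ("FTD vs CT", "MS vs CT", "HD vs CT", "AD vs CT", "ASD vs CT")
NEURO_GENES = ("SPP1", "APOE", "SERPINA1", "PINK1")
SEXES = ("F", "M")

XIST_GENE = "XIST"


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the synthetic generators.

    ``sparsity`` is the probability a (gene, cell type, condition) triple
    is dysregulated; ``effect_sigma`` the SD of the log2 fold-change
    stand-in; ``sig_scale`` the mean of the exponential -log10 p stand-in;
    ``tested_prob`` the chance a domino combination was tested at all.
    """

    seed: int = 0
    n_genes: int = 40
    cell_types: tuple[str, ...] = PBMC_CELL_TYPES
    conditions: tuple[str, ...] = AGE_SEX_CONDITIONS
    top_k: int = 25
    sparsity: float = 0.2
    domino_genes: tuple[str, ...] = NEURO_GENES
    domino_cell_types: tuple[str, ...] = BRAIN_CELL_TYPES
    contrasts: tuple[str, ...] = DISEASE_CONTRASTS
    split_levels: tuple[str, ...] = SEXES
    tested_prob: float = 0.9
    effect_sigma: float = 1.5
    sig_scale: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sparsity <= 1.0 or not 0.0 <= self.tested_prob <= 1.0:
            raise DegenerateConfig("sparsity and tested_prob must lie in [0, 1]")


def _require(config: FixtureConfig, **counts: int) -> None:
    empty = [name for name, n in counts.items() if n <= 0]
    if empty:
        raise DegenerateConfig(f"fixture config has zero {', '.join(empty)}")


def make_pbmc_like(config: FixtureConfig | None = None) -> LongTable:
    """Dice-mode table: gene dysregulation across PBMC populations.

    Returns a validated LongTable whose column (gene) factor order ranks
    the kept ``top_k`` genes by dysregulation score (number of present
    triples, descending; ties by name).  The XIST-like gene carries the
    background-group level ``"sex linked"``; all other genes ``"other"``.
    """
    config = config or FixtureConfig()
    _require(
        config,
        genes=config.n_genes,
        cell_types=len(config.cell_types),
        conditions=len(config.conditions),
    )
    rng = np.random.default_rng(config.seed)
    n_other = max(config.n_genes - 1, 0)
    genes = [f"GENE{i + 1:03d}" for i in range(n_other)] + [XIST_GENE]
    female = [c for c in config.conditions if c in FEMALE_CONDITIONS] or list(
        config.conditions[-2:]
    )

    rows = []
    for gene in genes:
        for ct in config.cell_types:
            for cond in config.conditions:
                if gene == XIST_GENE:
                    present = cond in female
                else:
                    present = rng.random() < config.sparsity
                if present:
                    rows.append(
                        {
                            "cell_type": ct,
                            "gene": gene,
                            "condition": cond,
                            "group": "sex linked" if gene == XIST_GENE else "other",
                        }
                    )
    df = pd.DataFrame(rows)
    score = df.groupby("gene").size()
    ranked = sorted(score.index, key=lambda g: (-int(score[g]), g))
    keep = ranked[: config.top_k]
    df = df[df["gene"].isin(keep)].reset_index(drop=True)

    roles = VariableRoles(row_var="cell_type", col_var="gene", dot_var="condition", bg_var="group")
    return validate_table(
        df,
        roles,
        mode="dice",
        factor_orders={
            "row": list(config.cell_types),
            "col": keep,
            "dot": list(config.conditions),
        },
    )


def make_zebra_like(config: FixtureConfig | None = None) -> LongTable:
    """Domino-mode table: key genes x brain cell types x disease contrasts,
    split by sex, with effect-size and significance stand-ins.

    Every combination yields a record; untested ones (probability
    ``1 - tested_prob``) carry missing values and render as hollow
    minimum-size pips.
    """
    config = config or FixtureConfig()
    _require(
        config,
        genes=len(config.domino_genes),
        cell_types=len(config.domino_cell_types),
        contrasts=len(config.contrasts),
        split_levels=len(config.split_levels),
    )
    rng = np.random.default_rng(config.seed)
    rows = []
    for ct in config.domino_cell_types:
        for gene in config.domino_genes:
            for contrast in config.contrasts:
                for sex in config.split_levels:
                    tested = rng.random() < config.tested_prob
                    lfc = rng.normal(0.0, config.effect_sigma) if tested else np.nan
                    sig = rng.exponential(config.sig_scale) if tested else np.nan
                    rows.append(
                        {
                            "cell_type": ct,
                            "gene": gene,
                            "contrast": contrast,
                            "sex": sex,
                            "log2fc": lfc,
                            "neg_log10_p": sig,
                        }
                    )
    df = pd.DataFrame(rows)
    roles = VariableRoles(
        row_var="cell_type",
        col_var="gene",
        contrast_var="contrast",
        split_var="sex",
        color_var="log2fc",
        size_var="neg_log10_p",
    )
    return validate_table(
        df,
        roles,
        mode="domino",
        factor_orders={
            "row": list(config.domino_cell_types),
            "col": list(config.domino_genes),
            "contrast": list(config.contrasts),
            "split": list(config.split_levels),
        },
    )


def write_fixture_csv(table: LongTable, path: str | Path, sep: str = ",") -> Path:
    """Write a fixture's records to the same CSV dialect the readers
    consume (floats at full repr precision; missing values empty)."""
    path = Path(path)
    table.records.to_csv(path, index=False, sep=sep)
    return path
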