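"""Synthetic chemogenomic screens with a planted compound module.

Real chemogenomic data score each compound against a genome-wide
deletion-strain collection, yielding a compound × gene matrix of
fitness-defect p-values. A group of compounds sharing a mechanism shows
significant interactions over a common gene set — a "module" — which is
exactly the structure the consensus-clustering prioritization is meant to
recover around a signature compound.

The generator emulates that: background entries are Uniform(0, 1) null
p-values; entries at (module compound, module gene) positions are drawn
Beta(effect_alpha, 1), a one-parameter family of p-value distributions that
is uniform at ``effect_alpha = 1`` and increasingly concentrated near zero
as ``effect_alpha`` → 0. Cells are then masked missing completely at random
at ``missing_rate``. By convention the first planted compound is the
signature compound (default identifier ``"lovastatin"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .matrixio import ChemGenMatrix

SIGNATURE_DEFAULT = "lovastatin"


@dataclass(frozen=True)
class SimParams:
    """Parameters of one synthetic screen.

    ``module_compounds`` counts the planted compounds *including* the
    signature; ``effect_alpha`` is the Beta shape of planted p-values
    (``< 1`` means signal; ``1`` is the exchangeable null).
    """

    n_compounds: int = 20
    n_genes: int = 100
    module_compounds: int = 4
    module_genes: int = 20
    effect_alpha: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0
    signature_id: str = SIGNATURE_DEFAULT

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_genes < 1:
            raise ParameterError("matrix dimensions must be positive")
        if not 1 <= self.module_compounds <= self.n_compounds:
            raise ParameterError("module_compounds must be in [1, n_compounds]")
        if not 0 <= self.module_genes <= self.n_genes:
            raise ParameterError("module_genes must be in [0, n_genes]")
        if not self.effect_alpha > 0:
            raise ParameterError("effect_alpha must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a generated screen, for recovery tests."""

    module_compound_ids: frozenset[str]
    module_gene_ids: frozenset[str]
    signature_id: str

    def __post_init__(self) -> None:
        if self.signature_id not in self.module_compound_ids:
            raise ParameterError("signature must belong to the planted module")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "module_compound_ids": sorted(self.module_compound_ids),
                    "module_gene_ids": sorted(self.module_gene_ids),
                    "signature_id": self.signature_id,
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )


def generate(params: SimParams) -> tuple[ChemGenMatrix, SimTruth]:
    """Draw one synthetic screen; bit-identical for identical ``params``.

    Planted block: Beta(effect_alpha, 1). Background: Uniform(0, 1).
    Missingness: i.i.d. Bernoulli(missing_rate), applied after generation.
    """
    rng = np.random.default_rng(params.seed)
    n, g = params.n_compounds, params.n_genes
    values = rng.uniform(0.0, 1.0, size=(n, g))
    mc, mg = params.module_compounds, params.module_genes
    if mc and mg:
        values[:mc, :mg] = rng.beta(params.effect_alpha, 1.0, size=(mc, mg))
    mask = rng.uniform(size=(n, g)) >= params.missing_rate

    width_c = max(2, len(str(n - 1)))
    width_g = max(2, len(str(g - 1)))
    compound_ids = [params.signature_id] + [
        f"cpd_{i:0{width_c}d}" for i in range(1, n)
    ]
    gene_ids = [f"gene_{j:0{width_g}d}" for j in range(g)]

    matrix = ChemGenMatrix(compound_ids, gene_ids, values, mask, "raw_p")
    truth = SimTruth(
        module_compound_ids=frozenset(compound_ids[:mc]),
        module_gene_ids=frozenset(gene_ids[:mg]),
        signature_id=params.signature_id,
    )
    return matrix, truth
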