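"""qPCR relative expression (ddCt) and RNA-pulldown enrichment formulas.

Relative expression uses the double-delta-Ct convention with a reference
(housekeeping) gene and a calibrator condition:

    dCt   = Ct_gene - Ct_reference            (per condition, replicate)
    ddCt  = mean dCt(condition) - mean dCt(calibrator)
    fold  = 2^(-ddCt)

RNA-immunoprecipitation / streptavidin-pulldown fold enrichment compares an
mRNA-targeting arm against a non-targeting arm, each input-normalized:

    fold = 2^(-ddCt(target arm)) / 2^(-ddCt(control arm)),

where per arm ddCt = (Ct_enriched,target - Ct_enriched,reference) -
(Ct_input,target - Ct_input,reference).  Percent input reports the
enriched fraction of the lysate reserved as input:

    %input = 100 * input_fraction * 2^(Ct_input - Ct_enriched).

No amplification-efficiency correction is applied (doubling per cycle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError, StructuralError

DEFAULT_REFERENCE_GENE = "RPL13A"

_LN2 = math.log(2.0)


def _delta_ct(table: pd.DataFrame, gene: str, condition: str,
              reference_gene: str) -> np.ndarray:
    """Per-replicate dCt = Ct_gene - Ct_reference for one condition."""
    sub = table[table["condition"] == condition]
    tgt = sub[sub["gene"] == gene].set_index("replicate")["Ct"]
    ref = sub[sub["gene"] == reference_gene].set_index("replicate")["Ct"]
    if tgt.empty:
        raise DataError(f"no Ct for gene {gene!r} in condition {condition!r}")
    missing = tgt.index.difference(ref.index)
    if not ref.index.size or missing.size:
        raise DataError(
            f"reference gene {reference_gene!r} missing in condition "
            f"{condition!r} (replicates {list(missing)})"
        )
    return (tgt - ref.loc[tgt.index]).to_numpy(dtype=float)


def ddct_relative_expression(
    table: pd.DataFrame,
    gene: str,
    condition: str,
    calibrator: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    per_replicate: bool = False,
) -> Tuple[float, float]:
    """Fold change 2^(-ddCt) of ``gene`` in ``condition`` vs ``calibrator``.

    Returns (fold, SEM of the fold).  The default convention averages dCt
    within each condition before differencing; ``per_replicate=True``
    instead forms a ddCt per replicate against the calibrator mean and
    averages the per-replicate folds' logs (identical point estimate,
    different error propagation).  The SEM is delta-method propagated:
    ``sem_fold = fold * ln(2) * sem_ddct``.
    """
    dct_cond = _delta_ct(table, gene, condition, reference_gene)
    dct_cal = _delta_ct(table, gene, calibrator, reference_gene)
    if condition == calibrator:
        return 1.0, 0.0
    if per_replicate:
        ddct_reps = dct_cond - dct_cal.mean()
        ddct = float(ddct_reps.mean())
        sem_ddct = float(ddct_reps.std(ddof=1) / math.sqrt(ddct_reps.size)) \
            if ddct_reps.size > 1 else 0.0
    else:
        ddct = float(dct_cond.mean() - dct_cal.mean())
        var = 0.0
        for arr in (dct_cond, dct_cal):
            if arr.size > 1:
                var += arr.var(ddof=1) / arr.size
        sem_ddct = math.sqrt(var)
    fold = 2.0 ** (-ddct)
    return fold, fold * _LN2 * sem_ddct


@dataclass
class RipQuant:
    """Input/enriched Ct values per experimental arm for a pulldown assay.

    ``arms`` maps arm name -> gene -> (Ct_input, Ct_enriched); the reference
    gene must be present in every arm.  ``input_fraction`` is the proportion
    of lysate reserved as the input sample.
    """

    arms: Dict[str, Dict[str, Tuple[float, float]]]
    reference_gene: str = DEFAULT_REFERENCE_GENE
    input_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.input_fraction <= 1.0:
            raise ConfigurationError("input_fraction must lie in (0, 1]")
        for arm, genes in self.arms.items():
            if self.reference_gene not in genes:
                raise StructuralError(
                    f"arm {arm!r} lacks the reference gene {self.reference_gene!r}"
                )

    def _ddct(self, arm: str, gene: str) -> float:
        if arm not in self.arms:
            raise StructuralError(f"arm {arm!r} absent from quantification")
        genes = self.arms[arm]
        if gene not in genes:
            raise DataError(f"gene {gene!r} absent from arm {arm!r}")
        ct_in_t, ct_en_t = genes[gene]
        ct_in_r, ct_en_r = genes[self.reference_gene]
        return (ct_en_t - ct_en_r) - (ct_in_t - ct_in_r)


def rip_fold_enrichment(
    quant: RipQuant,
    gene: str,
    target_arm: str = "AR g2",
    control_arm: str = "NT",
) -> float:
    """2^(-ddCt(target arm)) / 2^(-ddCt(control arm)) for one gene."""
    ddct_target = quant._ddct(target_arm, gene)
    ddct_control = quant._ddct(control_arm, gene)
    return 2.0 ** (-ddct_target) / 2.0 ** (-ddct_control)


def percent_input(quant: RipQuant, arm: str, gene: str) -> float:
    """Percentage of the input material recovered in the enriched fraction."""
    if arm not in quant.arms:
        raise StructuralError(f"arm {arm!r} absent from quantification")
    if gene not in quant.arms[arm]:
        raise DataError(f"gene {gene!r} absent from arm {arm!r}")
    ct_input, ct_enriched = quant.arms[arm][gene]
    return 100.0 * quant.input_fraction * 2.0 ** (ct_input - ct_enriched)
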