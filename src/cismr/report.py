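"""Presentation-layer rendering: OR/CI conventions and plot-ready tables.

Rendered output rounds ORs and CIs to 2 decimals and mediated proportions to
1 decimal; full precision is retained everywhere internally.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence


def or_from_beta(beta: float) -> float:
    """Odds ratio exp(beta); rounding happens only at render time."""
    return math.exp(beta)


def render_forest_data(results: Iterable, path, alpha: float = 0.05) -> None:
    """Write the underlying data of a forest plot.

    One row per MR result: label, OR, CI bounds, raw and FDR-adjusted p, and a
    significance flag (fdr_p < alpha), ordered by exposure then outcome.
    """
    rows = sorted(results, key=lambda r: (r.exposure, r.outcome, r.method))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label\tor\tci_low\tci_high\tpvalue\tfdr_pvalue\tsignificant\n")
        for r in rows:
            fdr = r.fdr_pvalue
            fh.write(
                "\t".join(
                    [
                        f"{r.exposure}->{r.outcome}",
                        f"{r.or_:.2f}",
                        f"{r.ci_low:.2f}",
                        f"{r.ci_high:.2f}",
                        f"{r.pvalue:.3g}",
                        "NA" if fdr is None else f"{fdr:.3g}",
                        "NA" if fdr is None else str(int(fdr < alpha)),
                    ]
                )
                + "\n"
            )


def render_mediation_table(mediation: Sequence, path) -> None:
    """Write mediation triples with the proportion as a 1-decimal percentage."""
    rows = sorted(mediation, key=lambda m: (m.target_label, m.mediator, m.outcome))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("target\tmediator\toutcome\tbeta1\tbeta2\tbeta3\tproportion_pct\n")
        for m in rows:
            fh.write(
                f"{m.target_label}\t{m.mediator}\t{m.outcome}\t"
                f"{m.beta1:.6g}\t{m.beta2:.6g}\t{m.beta3:.6g}\t{m.proportion_pct:.1f}\n"
            )
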