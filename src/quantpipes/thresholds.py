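"""Centralized significance cut-offs used by the three pipelines.

Every threshold that drives a call is collected here so it can be
overridden from configuration without touching pipeline code. The
strict/non-strict comparisons are part of the contract: the phospho
volcano uses ``p < 0.01`` with ``log2FC <= -1`` (inclusive), the bar
categories use strict ``< -0.5``, and BioID enrichment uses
``adjusted p < 0.05`` with ``log2FC >= 1`` (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class MetageneColorCodes:
    """Bonferroni-adjusted p-value cut-offs for the metagene bottom track."""

    red: float = 1e-15
    orange: float = 1e-10
    yellow: float = 1e-3

    def category(self, p_adj: float) -> str:
        if p_adj <= self.red:
            return "red"
        if p_adj <= self.orange:
            return "orange"
        if p_adj <= self.yellow:
            return "yellow"
        return "ns"


@dataclass
class SignificanceThresholds:
    """All printed cut-offs, configurable in one place.

    Attributes
    ----------
    volcano_p, volcano_log2fc
        A phosphosite is volcano-significant iff raw p < ``volcano_p``
        and log2FC <= ``volcano_log2fc`` (decrease; inclusive boundary).
    bar_log2fc
        Bar categories: *red* = p < ``volcano_p`` and log2FC < ``bar_log2fc``;
        *pink* = log2FC < ``bar_log2fc`` only; *none* otherwise.
    bioid_padj, bioid_log2fc, bioid_log2fc_inclusive
        BioID enrichment: adjusted p < ``bioid_padj`` and
        log2FC >= ``bioid_log2fc`` (inclusive by default; set
        ``bioid_log2fc_inclusive=False`` for the strict ">2-fold" reading).
    metagene
        Color codes for the per-bin Bonferroni-adjusted p-values.
    """

    volcano_p: float = 0.01
    volcano_log2fc: float = -1.0
    bar_log2fc: float = -0.5
    bioid_padj: float = 0.05
    bioid_log2fc: float = 1.0
    bioid_log2fc_inclusive: bool = True
    metagene: MetageneColorCodes = field(default_factory=MetageneColorCodes)
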