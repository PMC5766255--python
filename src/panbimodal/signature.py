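"""Anchor-coupled transcript signatures and discordant-cell detection.

A signature is the set of transcripts whose coupling coefficient with an
anchor analyte's posterior vector exceeds |r_b| > threshold, split into a
positive and a negative arm by the sign of r_b.  Discordant cells are those
assigned with high confidence to opposite mixture components in two layers
(e.g. mRNA high / protein low).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bimodal import MixtureFit
from .coupling import MIN_OVERLAP, coupling_coefficient


@dataclass
class SignatureMember:
    gene: str
    r_b: float

    @property
    def arm(self) -> str:
        return "positive" if self.r_b > 0 else "negative"


@dataclass
class GeneSignature:
    anchor: str
    threshold: float
    members: list[SignatureMember] = field(default_factory=list)

    @property
    def positive(self) -> list[str]:
        return [m.gene for m in self.members if m.arm == "positive"]

    @property
    def negative(self) -> list[str]:
        return [m.gene for m in self.members if m.arm == "negative"]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene": m.gene, "r_b": m.r_b, "arm": m.arm} for m in self.members])


@dataclass
class DiscordantCall:
    cell_id: str
    mrna_state: str  # low | high | uncertain
    protein_state: str
    posterior_mrna: float
    posterior_protein: float


def derive_signature(
    anchor_fit: MixtureFit,
    mrna_posteriors: pd.DataFrame,
    threshold: float = 0.5,
    min_overlap: int = MIN_OVERLAP,
) -> GeneSignature:
    """Transcripts coupled to the anchor at |r_b| > threshold (strict).

    The anchor must itself be bimodal.  Members are sorted by |r_b|
    descending; arm is positive for r_b > 0, negative otherwise.
    """
    if not anchor_fit.is_bimodal:
        raise ValueError(f"anchor {anchor_fit.analyte_id!r} is not bimodal")
    anchor_post = anchor_fit.posteriors
    members = []
    for gene in mrna_posteriors.index:
        if gene == anchor_fit.analyte_id:
            continue
        pB = mrna_posteriors.loc[gene].reindex(anchor_post.index)
        r, n, _ = coupling_coefficient(anchor_post, pB, min_overlap)
        if np.isfinite(r) and abs(r) > threshold:
            members.append(SignatureMember(gene=str(gene), r_b=float(r)))
    members.sort(key=lambda m: abs(m.r_b), reverse=True)
    return GeneSignature(anchor=anchor_fit.analyte_id, threshold=threshold,
                         members=members)


def _state(p: float, conf: float) -> str:
    if p >= 1 - conf:
        return "high"
    if p <= conf:
        return "low"
    return "uncertain"


def call_discordant(
    mrna_posterior: pd.Series,
    protein_posterior: pd.Series,
    conf: float = 0.1,
) -> tuple[list[DiscordantCall], pd.DataFrame]:
    """High-confidence state calls per cell and the (mrna, protein) summary.

    A cell is high if its posterior >= 1-conf, low if <= conf, else
    uncertain.  Cells missing either posterior are dropped.  The summary
    counts every (mrna_state, protein_state) combination; the (+-)
    discordant set is (high, low).
    """
    if conf >= 0.5:
        raise ValueError("conf must be < 0.5")
    protein_posterior = protein_posterior.reindex(mrna_posterior.index)
    ok = mrna_posterior.notna() & protein_posterior.notna()
    calls = [DiscordantCall(
        cell_id=str(c),
        mrna_state=_state(float(mrna_posterior[c]), conf),
        protein_state=_state(float(protein_posterior[c]), conf),
        posterior_mrna=float(mrna_posterior[c]),
        posterior_protein=float(protein_posterior[c]),
    ) for c in mrna_posterior.index[ok]]
    states = ["high", "low", "uncertain"]
    summary = pd.DataFrame(0, index=states, columns=states, dtype=int)
    summary.index.name = "mrna_state"
    summary.columns.name = "protein_state"
    for c in calls:
        summary.loc[c.mrna_state, c.protein_state] += 1
    return calls, summary


def discordant_cells(calls: list[DiscordantCall]) -> list[str]:
    """Cells in the (+-) set: mRNA high, protein low."""
    return [c.cell_id for c in calls
            if c.mrna_state == "high" and c.protein_state == "low"]


def export_updown(sig: GeneSignature, direction: str = "induce"
                  ) -> tuple[list[str], list[str]]:
    """(up, down) gene lists for signature-query services.

    ``induce`` mode up-regulates the negative arm and down-regulates the
    positive arm; ``reverse`` swaps them.  Symbols are deduplicated
    (order-preserving) and uppercased.
    """
    if not sig.members:
        raise ValueError("empty signature")

    def clean(genes: list[str]) -> list[str]:
        seen, out = set(), []
        for g in genes:
            u = g.upper()
            if u not in seen:
                seen.add(u)
                out.append(u)
        return out

    pos, neg = clean(sig.positive), clean(sig.negative)
    if not pos or not neg:
        warnings.warn("one signature arm is empty", stacklevel=2)
    if direction == "induce":
        return neg, pos
    if direction == "reverse":
        return pos, neg
    raise ValueError(f"unknown direction {direction!r}")


def write_gene_lists(up: list[str], down: list[str], prefix: str,
                     name: str = "signature") -> None:
    """Write newline-delimited up/down lists and a two-line GMT file."""
    with open(f"{prefix}_up.txt", "w") as fh:
        fh.write("\n".join(up) + ("\n" if up else ""))
    with open(f"{prefix}_down.txt", "w") as fh:
        fh.write("\n".join(down) + ("\n" if down else ""))
    with open(f"{prefix}.gmt", "w") as fh:
        fh.write("\t".join([f"{name}_up", "na", *up]) + "\n")
        fh.write("\t".join([f"{name}_down", "na", *down]) + "\n")
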