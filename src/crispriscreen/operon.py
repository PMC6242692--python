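"""Polar-effect-aware reclassification of depleted genes within operons.

dCas9 silencing is polar: blocking transcription of one gene in an
operon also silences every downstream gene of the transcription unit.
A depleted gene is therefore only *confidently* essential when no
observed gene downstream of it in the same TU is depleted; a depleted
gene with a depleted observed gene downstream remains *potentially*
essential (its own signal may be entirely polar).  A non-depleted gene
upstream of a depleted gene suggests an internal promoter driving the
downstream gene independently.

Genes with no coding-strand guides are "unobserved": they are skipped
when scanning downstream (they neither rescue nor demote a call) and
never receive a call themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "OperonCall",
    "OperonClassifier",
    "classify_tu",
    "classify_genome",
    "polar_attribution",
    "CONFIDENT",
    "POTENTIAL",
    "NON_ESSENTIAL",
    "INTERNAL_PROMOTER",
    "UNOBSERVED",
]

CONFIDENT = "confidently_essential"
POTENTIAL = "potentially_essential"
NON_ESSENTIAL = "non_essential"
INTERNAL_PROMOTER = "internal_promoter_candidate"
UNOBSERVED = "unobserved"


@dataclass(frozen=True)
class OperonCall:
    gene: str
    depleted: bool | None  # None = unobserved
    category: str
    tu_id: str | None
    evidence: str = ""


def classify_tu(
    tu_genes: list[str],
    depleted_flags: dict[str, bool | None],
    tu_id: str | None = None,
) -> list[OperonCall]:
    """Classify one transcription unit (genes ordered 5'->3').

    ``depleted_flags`` maps gene -> True (depleted), False (observed
    clean) or None (unobserved: no coding-strand guides).  A missing
    gene raises.
    """
    missing = [g for g in tu_genes if g not in depleted_flags]
    if missing:
        raise KeyError(
            f"TU {tu_id or '?'}: no depletion flag for gene(s) {missing}; "
            "mark coverage holes as unobserved (None)"
        )
    flags = [depleted_flags[g] for g in tu_genes]
    calls: list[OperonCall] = []
    for i, (gene, flag) in enumerate(zip(tu_genes, flags)):
        observed_down = [
            (g, f) for g, f in zip(tu_genes[i + 1 :], flags[i + 1 :])
            if f is not None
        ]
        down_depleted = [g for g, f in observed_down if f]
        if flag is None:
            calls.append(
                OperonCall(gene, None, UNOBSERVED, tu_id, "no coding-strand guides")
            )
        elif flag:
            # polar silencing runs downstream, so a depleted gene is only
            # uncertain while its depleted run continues: the next
            # *observed* gene being clean proves any further-downstream
            # depletion is independently driven
            next_flag = observed_down[0][1] if observed_down else False
            if next_flag:
                calls.append(
                    OperonCall(
                        gene, True, POTENTIAL, tu_id,
                        "depleted run continues downstream: "
                        f"{','.join(down_depleted)}",
                    )
                )
            else:
                calls.append(
                    OperonCall(gene, True, CONFIDENT, tu_id,
                               "most downstream gene of its depleted run")
                )
        else:
            if down_depleted:
                calls.append(
                    OperonCall(
                        gene, False, INTERNAL_PROMOTER, tu_id,
                        "clean upstream of depleted "
                        f"{','.join(down_depleted)}; internal promoter likely",
                    )
                )
            else:
                calls.append(OperonCall(gene, False, NON_ESSENTIAL, tu_id, ""))
    return calls


class OperonClassifier(BaseEstimator):
    """Genome-wide polar-effect classification over a TU table.

    ``fit`` takes a TU table (columns ``tu_id, gene, rank``) and a
    per-gene depleted flag mapping/Series.  Genes absent from every TU
    are treated as monocistronic: depleted ones are confidently
    essential.  A gene present in several TUs is classified under each
    and flagged in the evidence.
    """

    def fit(
        self,
        tus: pd.DataFrame,
        depleted_flags: pd.Series | dict,
    ) -> "OperonClassifier":
        flags = dict(depleted_flags)
        calls: list[OperonCall] = []
        seen: set[str] = set()
        multi = (
            tus.groupby("gene")["tu_id"].nunique().loc[lambda s: s > 1].index
            if len(tus)
            else []
        )
        for tu_id, grp in tus.groupby("tu_id"):
            ordered = grp.sort_values("rank")["gene"].tolist()
            tu_flags = {g: flags.get(g, None) for g in ordered}
            for call in classify_tu(ordered, tu_flags, str(tu_id)):
                if call.gene in set(multi):
                    call = OperonCall(
                        call.gene, call.depleted, call.category, call.tu_id,
                        (call.evidence + "; gene in multiple TUs").strip("; "),
                    )
                calls.append(call)
            seen.update(ordered)
        for gene, flag in flags.items():
            if gene in seen or flag is None:
                continue
            category = CONFIDENT if flag else NON_ESSENTIAL
            calls.append(OperonCall(gene, bool(flag), category, None, "monocistronic"))

        table = pd.DataFrame(
            [
                {"gene": c.gene, "tu_id": c.tu_id, "depleted": c.depleted,
                 "category": c.category, "evidence": c.evidence}
                for c in calls
            ]
        )
        self.calls_ = table
        self.summary_ = self._summarize(table)
        return self

    @staticmethod
    def _summarize(table: pd.DataFrame) -> dict[str, int]:
        # a gene in several TUs counts once: potential beats confident
        per_gene = (
            table[table["depleted"] == True]  # noqa: E712
            .groupby("gene")["category"]
            .agg(lambda cats: POTENTIAL if (cats == POTENTIAL).any() else CONFIDENT)
        )
        n_ip_tus = table.loc[
            table["category"] == INTERNAL_PROMOTER, "tu_id"
        ].nunique()
        return {
            "n_confident": int((per_gene == CONFIDENT).sum()),
            "n_uncertain": int((per_gene == POTENTIAL).sum()),
            "n_internal_promoter_tus": int(n_ip_tus),
        }


def classify_genome(
    tus: pd.DataFrame, depleted_flags: pd.Series | dict
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply :func:`classify_tu` across all TUs; monocistronic depleted
    genes are confidently essential.  Returns (call table, summary)."""
    clf = OperonClassifier().fit(tus, depleted_flags)
    return clf.calls_, clf.summary_


def polar_attribution(
    calls: pd.DataFrame,
    tus: pd.DataFrame,
    essential_labels: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, float]:
    """Attribute potentially-polar depletion to downstream genes.

    Each potentially-essential gene is annotated with the downstream
    depleted gene(s) of its TU; when essential/near-essential labels are
    supplied, the attribution is restricted to labelled downstream genes
    and the summary fraction counts depleted genes *lacking their own
    label* whose depletion a downstream labelled gene can explain, over
    all depleted genes (the polar false-positive fraction).
    """
    labels = dict(essential_labels) if essential_labels is not None else None
    order = {
        (r.tu_id, r.gene): r.rank for r in tus.itertuples()
    }
    tu_members: dict[str, list[str]] = {
        str(t): grp.sort_values("rank")["gene"].tolist()
        for t, grp in tus.groupby("tu_id")
    }
    depleted = set(calls.loc[calls["depleted"] == True, "gene"])  # noqa: E712

    rows = []
    explained: set[str] = set()
    for r in calls.itertuples():
        if not r.depleted or r.tu_id is None or pd.isna(r.tu_id):
            continue
        members = tu_members.get(str(r.tu_id), [])
        if r.gene not in members:
            continue
        i = members.index(r.gene)
        down = members[i + 1 :]
        down_depleted = [g for g in down if g in depleted]
        if labels is not None:
            attributed = [g for g in down if labels.get(g)]
        else:
            attributed = down_depleted
        rows.append(
            {"gene": r.gene, "tu_id": r.tu_id, "category": r.category,
             "attributed_to": ",".join(attributed)}
        )
        own_label = labels.get(r.gene) if labels is not None else False
        if attributed and not own_label:
            explained.add(r.gene)
    attribution = pd.DataFrame(rows, columns=["gene", "tu_id", "category", "attributed_to"])
    n_depleted = len(depleted)
    fraction = len(explained) / n_depleted if n_depleted else 0.0
    return attribution, fraction
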