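"""Tissue-targeting statistics: content normalization, relative targeting
efficiency (RTE) and target classification.

For each group, a tissue's exposure fraction is its AUC over the sum of
AUCs across all tissues in the design (sex-specific organs simply
contribute their single-sex AUC; an absent organ contributes 0).  The RTE
of a tissue is

    rte = frac_salt / frac_crude - 1

so rte > 0 means the salt-processed preparation shifts a larger share of
total tissue exposure into that tissue.  The statistic is scale-free: it is
unchanged when all of one group's AUCs are multiplied by a constant.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import TargetingError
from .nca import AUCResult


@dataclass(frozen=True)
class RTEResult:
    compound: str
    tissue: str
    auc_crude: float
    auc_salt_normalized: float
    frac_crude: float
    frac_salt: float
    rte: float
    targeted: bool
    degenerate: bool = False  # frac_crude == 0 with frac_salt > 0


def normalize_salt_auc(auc_salt_raw: float, content_salt: float,
                       content_crude: float) -> float:
    """Divide the salt-group AUC by the salt/crude extract content ratio.

    Removes the in-vitro dose-content difference between the two extracts
    so that tissue differences reflect distribution, not content.
    """
    if not content_crude > 0:
        raise TargetingError(f"content_crude must be > 0, got {content_crude}")
    if not content_salt > 0:
        raise TargetingError(f"content_salt must be > 0, got {content_salt}")
    return auc_salt_raw / (content_salt / content_crude)


def _auc_value(entry) -> float:
    return entry.auc if isinstance(entry, AUCResult) else float(entry)


def compute_rte(auc_by_tissue_salt: Mapping[str, AUCResult | float],
                auc_by_tissue_crude: Mapping[str, AUCResult | float],
                compound: str = "") -> list[RTEResult]:
    """Per-tissue RTE from (already normalized) salt and crude AUC maps.

    Both maps must cover the same tissue set.  Fractions are computed
    within each group against that group's own AUC sum; a tissue with zero
    crude fraction but positive salt fraction gets an infinite-RTE sentinel
    with the ``degenerate`` flag.
    """
    salt_tissues = set(auc_by_tissue_salt)
    crude_tissues = set(auc_by_tissue_crude)
    if salt_tissues != crude_tissues:
        raise TargetingError(
            f"tissue sets differ: salt-only {sorted(salt_tissues - crude_tissues)}, "
            f"crude-only {sorted(crude_tissues - salt_tissues)}")
    if not compound:
        for entry in list(auc_by_tissue_salt.values()):
            if isinstance(entry, AUCResult):
                compound = entry.compound
                break

    salt = {t: _auc_value(v) for t, v in auc_by_tissue_salt.items()}
    crude = {t: _auc_value(v) for t, v in auc_by_tissue_crude.items()}
    for label, aucs in (("salt", salt), ("crude", crude)):
        if any(v < 0 for v in aucs.values()):
            raise TargetingError(f"negative AUC in {label} group")
    sum_salt = sum(salt.values())
    sum_crude = sum(crude.values())
    if sum_salt == 0 or sum_crude == 0:
        raise TargetingError("AUC sum is zero in at least one group")

    results = []
    for tissue in sorted(salt):
        frac_salt = salt[tissue] / sum_salt
        frac_crude = crude[tissue] / sum_crude
        if frac_crude == 0:
            if frac_salt == 0:
                rte, degenerate = 0.0, False
            else:
                rte, degenerate = math.inf, True
        else:
            rte, degenerate = frac_salt / frac_crude - 1.0, False
        results.append(RTEResult(
            compound=compound, tissue=tissue,
            auc_crude=crude[tissue], auc_salt_normalized=salt[tissue],
            frac_crude=frac_crude, frac_salt=frac_salt,
            rte=rte, targeted=rte > 0, degenerate=degenerate))
    return results


def classify_targets(results: Sequence[RTEResult],
                     threshold: float = 0.0) -> dict[str, list[RTEResult]]:
    """Per compound, the tissues with rte > threshold, sorted descending by rte."""
    by_compound: dict[str, list[RTEResult]] = {}
    for result in results:
        by_compound.setdefault(result.compound, []).append(result)
    ranked = {}
    for compound, items in by_compound.items():
        targets = [r for r in items if r.rte > threshold]
        targets.sort(key=lambda r: r.rte, reverse=True)
        ranked[compound] = targets
    return ranked


# ---------------------------------------------------------------------------
# report writers

RTE_COLUMNS = ("compound", "tissue", "auc_crude", "auc_salt_normalized",
               "frac_crude", "frac_salt", "rte", "targeted")


def write_rte_table(results: Sequence[RTEResult], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(RTE_COLUMNS)
        for r in results:
            writer.writerow([r.compound, r.tissue, repr(r.auc_crude),
                             repr(r.auc_salt_normalized), repr(r.frac_crude),
                             repr(r.frac_salt), repr(r.rte), r.targeted])


def write_target_report(results: Sequence[RTEResult], path,
                        threshold: float = 0.0) -> None:
    """Markdown report of ranked target tissues per compound."""
    ranked = classify_targets(results, threshold=threshold)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# Target-tissue ranking (rte > %g)\n\n" % threshold)
        for compound in sorted(ranked):
            targets = ranked[compound]
            handle.write(f"## {compound}\n\n")
            if not targets:
                handle.write("no targeted tissues\n\n")
                continue
            for rank, r in enumerate(targets, start=1):
                rte = "inf" if math.isinf(r.rte) else f"{r.rte:.3f}"
                handle.write(f"{rank}. {r.tissue} (rte = {rte})\n")
            handle.write("\n")
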