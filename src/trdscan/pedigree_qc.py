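"""Trio construction and quality control.

Builds parent-parent-child trios from the pedigree, screens them for
Mendelian-inconsistent parent assignments, and applies marker-level
exclusions (call rate, founder informativeness).  Individuals whose trio
shows an excess of Mendelian errors are removed together with their
descendants in the analyzed generations, mirroring how wrongly assigned
parents propagate through a multigenerational design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import HET, HOM_A, HOM_B, MISSING, GenotypeMatrix, Pedigree

#: default Mendelian-error fraction above which a parent assignment is rejected
DEFAULT_MISASSIGNMENT_THRESHOLD = 0.05


@dataclass
class Trio:
    """A child with resolved sire/dam links plus Mendelian-check tallies."""

    child_id: str
    sire_id: str
    dam_id: str
    n_checked: int = 0
    n_mendel_errors: int = 0

    def __post_init__(self):
        if self.n_mendel_errors > self.n_checked:
            raise ValueError("n_mendel_errors > n_checked")


@dataclass
class QcReport:
    """Machine-readable record of every QC removal and the thresholds used."""

    removed_individuals: list[tuple[str, str]] = field(default_factory=list)
    removed_markers: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "removed_individuals": [list(t) for t in self.removed_individuals],
            "removed_markers": [list(t) for t in self.removed_markers],
            "thresholds": self.thresholds,
        }


def build_trios(
    pedigree: Pedigree,
    generation: int,
    genotypes: GenotypeMatrix | None = None,
) -> list[Trio]:
    """One trio per individual of ``generation`` with both parents known.

    When ``genotypes`` is given, trios whose members are not all genotyped
    are excluded as well (the transmission test needs all three).
    """
    trios: list[Trio] = []
    for iid in pedigree.individuals_of_generation(generation):
        rec = pedigree.record(iid)
        if rec.sire_id is None or rec.dam_id is None:
            continue
        if genotypes is not None and not all(
            genotypes.has_individual(x) for x in (iid, rec.sire_id, rec.dam_id)
        ):
            continue
        trios.append(Trio(iid, rec.sire_id, rec.dam_id))
    return trios


def _mendel_error_mask(sire: np.ndarray, dam: np.ndarray, child: np.ndarray) -> np.ndarray:
    """Boolean mask of markers where the child is impossible given the parents."""
    err = np.zeros(child.shape, dtype=bool)
    # child homozygous for an allele a parent cannot contribute
    err |= (child == HOM_A) & ((sire == HOM_B) | (dam == HOM_B))
    err |= (child == HOM_B) & ((sire == HOM_A) | (dam == HOM_A))
    # heterozygous child from two identical homozygotes
    err |= (child == HET) & (sire == HOM_A) & (dam == HOM_A)
    err |= (child == HET) & (sire == HOM_B) & (dam == HOM_B)
    return err


def mendelian_error_rate(trio: Trio, genotypes: GenotypeMatrix) -> float:
    """Fraction of checkable markers with a Mendelian-impossible child call.

    Checkable = informative markers where all three trio members are
    non-missing.  The trio's tallies are updated in place.
    """
    sire = genotypes.row(trio.sire_id)
    dam = genotypes.row(trio.dam_id)
    child = genotypes.row(trio.child_id)
    informative = np.array([m.informative for m in genotypes.markers], dtype=bool)
    complete = (sire != MISSING) & (dam != MISSING) & (child != MISSING) & informative
    n_checked = int(complete.sum())
    if n_checked == 0:
        raise ValueError(
            f"trio {trio.child_id}: no overlapping non-missing informative markers"
        )
    errors = _mendel_error_mask(sire, dam, child) & complete
    trio.n_checked = n_checked
    trio.n_mendel_errors = int(errors.sum())
    return trio.n_mendel_errors / n_checked


def flag_misassigned(
    trios: list[Trio],
    genotypes: GenotypeMatrix,
    threshold: float = DEFAULT_MISASSIGNMENT_THRESHOLD,
    pedigree: Pedigree | None = None,
) -> QcReport:
    """Flag trios whose Mendelian-error rate exceeds ``threshold``.

    Flagged children are removed; when a ``pedigree`` is supplied the
    removal cascades to all descendants of the flagged individual inside
    the pedigree (offspring of a wrongly assigned parent inherit the
    uncertainty).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    report = QcReport(thresholds={"misassignment_threshold": threshold})
    flagged: list[str] = []
    for trio in trios:
        rate = mendelian_error_rate(trio, genotypes)
        if rate > threshold:
            report.removed_individuals.append(
                (trio.child_id, f"mendel_error_rate={rate:.4f}")
            )
            flagged.append(trio.child_id)
    if pedigree is not None:
        already = {iid for iid, _ in report.removed_individuals}
        for iid in flagged:
            for desc in sorted(pedigree.descendants_of(iid)):
                if desc not in already:
                    report.removed_individuals.append((desc, f"descendant_of:{iid}"))
                    already.add(desc)
    return report


def marker_qc(
    genotypes: GenotypeMatrix, min_call_rate: float = 0.9
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers below the call-rate threshold or uninformative between founders."""
    if not 0 < min_call_rate <= 1:
        raise ValueError("min_call_rate must be in (0,1]")
    report = QcReport(thresholds={"min_call_rate": min_call_rate})
    rates = genotypes.call_rates()
    keep: list[str] = []
    for j, m in enumerate(genotypes.markers):
        if not m.informative:
            report.removed_markers.append((m.marker_id, "uninformative"))
        elif rates[j] < min_call_rate:
            report.removed_markers.append((m.marker_id, f"call_rate={rates[j]:.3f}"))
        else:
            keep.append(m.marker_id)
    return genotypes.subset_markers(keep), report
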