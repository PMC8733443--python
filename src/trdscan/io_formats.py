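"""Canonical in-memory data model and readers/writers for genotypes,
pedigrees, marker maps, gene annotations and result tables.

Genotype calls are founder-polarized: ``HOM_A`` means homozygous for the
allele carried by founder 1 (the BFMI-like line in the motivating cross),
``HOM_B`` homozygous for founder 2's allele (B6N-like).  Internal
coordinates are 1-based inclusive base pairs; BED export converts to
0-based half-open.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# genotype codes (int8)
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
MISSING: int = -1

_TSV_CODE = {HOM_A: "A", HET: "H", HOM_B: "B", MISSING: "-"}
_TSV_DECODE = {"A": HOM_A, "H": HET, "B": HOM_B, "-": MISSING, ".": MISSING}

#: default autosome set (mouse); chromosome names are opaque strings
MOUSE_AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 20))


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def chrom_sort_key(chrom: str):
    """Sort numeric chromosome names numerically, others lexically after."""
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


@dataclass(frozen=True)
class MarkerInfo:
    """A biallelic marker with map position.

    ``informative`` is True when the two founders carry different alleles;
    only informative markers can enter transmission tests.
    """

    marker_id: str
    chromosome: str
    position_bp: int
    informative: bool = True

    def __post_init__(self):
        if self.position_bp < 1:
            raise ValueError(f"position_bp must be >= 1 ({self.marker_id})")


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of founder-coded biallelic calls.

    ``calls`` is an int8 array of shape (n_individuals, n_markers) with
    values in {HOM_A, HET, HOM_B, MISSING}.
    """

    individuals: list[str]
    markers: list[MarkerInfo]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        valid = np.isin(self.calls, (HOM_A, HET, HOM_B, MISSING))
        if not valid.all():
            raise ValueError("calls contain codes outside {HOM_A, HET, HOM_B, MISSING}")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids")
        self._ind_index = {iid: i for i, iid in enumerate(self.individuals)}
        self._marker_index = {m.marker_id: j for j, m in enumerate(self.markers)}

    # -- lookups -----------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def individual_index(self, individual_id: str) -> int:
        return self._ind_index[individual_id]

    def marker_index(self, marker_id: str) -> int:
        return self._marker_index[marker_id]

    def has_individual(self, individual_id: str) -> bool:
        return individual_id in self._ind_index

    def get(self, individual_id: str, marker_id: str) -> int:
        return int(self.calls[self._ind_index[individual_id], self._marker_index[marker_id]])

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self._marker_index[marker_id]]

    def row(self, individual_id: str) -> np.ndarray:
        return self.calls[self._ind_index[individual_id], :]

    # -- derived per-marker quantities ------------------------------------
    def call_rates(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return (self.calls != MISSING).mean(axis=0)

    def genotype_counts(self, marker_id: str, individuals: Sequence[str] | None = None):
        """(n_AA, n_AB, n_BB) among the given individuals (default all)."""
        col = self.column(marker_id)
        if individuals is not None:
            idx = [self._ind_index[i] for i in individuals]
            col = col[idx]
        return int((col == HOM_A).sum()), int((col == HET).sum()), int((col == HOM_B).sum())

    # -- subsetting --------------------------------------------------------
    def subset_markers(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self._marker_index[m] for m in marker_ids]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            markers=[self.markers[j] for j in idx],
            calls=self.calls[:, idx].copy(),
        )

    def subset_individuals(self, individual_ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self._ind_index[i] for i in individual_ids]
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in idx],
            markers=list(self.markers),
            calls=self.calls[idx, :].copy(),
        )

    def sorted_by_map(self) -> "GenotypeMatrix":
        order = sorted(
            range(self.n_markers),
            key=lambda j: (chrom_sort_key(self.markers[j].chromosome), self.markers[j].position_bp),
        )
        return GenotypeMatrix(
            individuals=list(self.individuals),
            markers=[self.markers[j] for j in order],
            calls=self.calls[:, order].copy(),
        )

    def swap_polarization(self) -> "GenotypeMatrix":
        """Return a copy with founder A and B roles exchanged (HOM_A <-> HOM_B)."""
        calls = self.calls.copy()
        a = calls == HOM_A
        calls[calls == HOM_B] = HOM_A
        calls[a] = HOM_B
        return GenotypeMatrix(list(self.individuals), list(self.markers), calls)


@dataclass(frozen=True)
class PedigreeRecord:
    individual_id: str
    sire_id: str | None
    dam_id: str | None
    generation: int
    sex: str = "unknown"  # {"M", "F", "unknown"}


@dataclass
class Pedigree:
    """Validated pedigree: acyclic, parents present, parent generation < child."""

    records: list[PedigreeRecord]

    def __post_init__(self):
        self._by_id: dict[str, PedigreeRecord] = {}
        for rec in self.records:
            if rec.individual_id in self._by_id:
                raise ValueError(f"duplicate individual id {rec.individual_id!r}")
            self._by_id[rec.individual_id] = rec
        for rec in self.records:
            for parent in (rec.sire_id, rec.dam_id):
                if parent is None:
                    continue
                if parent == rec.individual_id:
                    raise ValueError(f"{rec.individual_id!r} is listed as its own parent")
                if parent not in self._by_id:
                    raise ValueError(f"parent {parent!r} of {rec.individual_id!r} not in pedigree")
                if self._by_id[parent].generation >= rec.generation:
                    raise ValueError(
                        f"parent {parent!r} (gen {self._by_id[parent].generation}) not older "
                        f"than child {rec.individual_id!r} (gen {rec.generation})"
                    )
        self._check_acyclic()

    def _check_acyclic(self):
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]):
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ValueError(f"pedigree cycle involving {iid!r}")
            state[iid] = 0
            rec = self._by_id[iid]
            for parent in (rec.sire_id, rec.dam_id):
                if parent is not None:
                    visit(parent, stack + [iid])
            state[iid] = 1

        for iid in self._by_id:
            visit(iid, [])

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def record(self, individual_id: str) -> PedigreeRecord:
        return self._by_id[individual_id]

    def generations(self) -> list[int]:
        return sorted({r.generation for r in self.records})

    def individuals_of_generation(self, generation: int) -> list[str]:
        return [r.individual_id for r in self.records if r.generation == generation]

    def children_of(self, individual_id: str) -> list[str]:
        return [
            r.individual_id
            for r in self.records
            if individual_id in (r.sire_id, r.dam_id)
        ]

    def descendants_of(self, individual_id: str) -> set[str]:
        out: set[str] = set()
        frontier = [individual_id]
        while frontier:
            nxt: list[str] = []
            for iid in frontier:
                for child in self.children_of(iid):
                    if child not in out:
                        out.add(child)
                        nxt.append(child)
            frontier = nxt
        return out


_PREDICTED_GENE_RE = re.compile(r"(^Gm\d+$)|(Rik$)")


def is_predicted_symbol(gene_id: str) -> bool:
    """True for GM/RIKEN-style predicted gene symbols (Gm#### or ...Rik)."""
    return bool(_PREDICTED_GENE_RE.search(gene_id))


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval with its nonsynonymous-SNP burden."""

    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    biotype: str = "protein_coding"
    nssnp_count: int = 0
    predicted_flag: bool | None = None

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(f"start_bp > end_bp for {self.gene_id}")
        if self.nssnp_count < 0:
            raise ValueError(f"negative nssnp_count for {self.gene_id}")
        if self.predicted_flag is None:
            object.__setattr__(self, "predicted_flag", is_predicted_symbol(self.gene_id))


@dataclass(frozen=True)
class PpiEdge:
    """Undirected protein-protein interaction edge; gene order is normalized."""

    gene_a: str
    gene_b: str
    score: float = 0.0

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-edge on {self.gene_a}")
        if self.gene_b < self.gene_a:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


# ---------------------------------------------------------------------------
# genotype readers
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    format: str,
    founder_a_id: str | None = None,
    founder_b_id: str | None = None,
) -> GenotypeMatrix:
    """Read genotypes and polarize them to the two founder lines.

    Parameters
    ----------
    path
        Input file (for ``ped_map`` give the ``.ped`` path; the ``.map`` file
        is expected alongside with the same stem).
    format
        One of ``vcf``, ``ped_map``, ``tsv``.
    founder_a_id, founder_b_id
        Sample ids of founder 1 and founder 2.  When given, calls are
        re-coded so that ``HOM_A`` is homozygous for founder 1's allele;
        markers where the founders agree are flagged uninformative.  When a
        founder call is missing at a marker the arbitrary input polarization
        is kept and a warning is emitted.
    """
    path = Path(path)
    if format == "vcf":
        gm = _read_vcf(path)
    elif format == "ped_map":
        gm = _read_ped_map(path)
    elif format == "tsv":
        gm = _read_tsv(path)
    else:
        raise FormatError(f"unknown genotype format {format!r}")
    if (founder_a_id is None) != (founder_b_id is None):
        raise ValueError("give both founder ids or neither")
    if founder_a_id is not None:
        gm = polarize_to_founders(gm, founder_a_id, founder_b_id)
    return gm


def polarize_to_founders(gm: GenotypeMatrix, founder_a_id: str, founder_b_id: str) -> GenotypeMatrix:
    """Re-code calls so HOM_A is homozygous for founder 1's allele.

    Markers where the founders carry the same allele (or a founder is
    heterozygous, impossible for a fully inbred line) are flagged
    ``informative=False``; markers where a founder call is missing keep the
    arbitrary input polarization with a warning.
    """
    for fid in (founder_a_id, founder_b_id):
        if not gm.has_individual(fid):
            raise ValueError(f"founder {fid!r} not genotyped")
    fa = gm.row(founder_a_id)
    fb = gm.row(founder_b_id)
    calls = gm.calls.copy()
    markers: list[MarkerInfo] = []
    n_unpolarizable = 0
    for j, m in enumerate(gm.markers):
        a, b = int(fa[j]), int(fb[j])
        informative = True
        if a == MISSING or b == MISSING:
            n_unpolarizable += 1
        elif a == HET or b == HET:
            informative = False
        elif a == b:
            informative = False
        else:
            if a == HOM_B:  # founder 1 carries the "B"-coded allele: flip column
                col = calls[:, j]
                hom_a = col == HOM_A
                col[col == HOM_B] = HOM_A
                col[hom_a] = HOM_B
        markers.append(replace(m, informative=informative))
    if n_unpolarizable:
        warnings.warn(
            f"{n_unpolarizable} markers could not be founder-polarized "
            "(missing founder call); arbitrary polarization kept"
        )
    return GenotypeMatrix(list(gm.individuals), markers, calls)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: heavy import

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    markers: list[MarkerInfo] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        if var.ploidy != 2:
            raise FormatError(f"ploidy {var.ploidy} != 2 at {var.CHROM}:{var.POS}")
        # gts012: 0=HOM_REF, 1=HET, 2=HOM_ALT, 3=unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        markers.append(MarkerInfo(mid, str(var.CHROM), int(var.POS)))
        cols.append(gt)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic VCF records")
    calls = (
        np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, markers, calls)


def _read_ped_map(ped_path: Path) -> GenotypeMatrix:
    map_path = ped_path.with_suffix(".map")
    markers: list[MarkerInfo] = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"MAP line with {len(parts)} fields: {line.rstrip()}")
            chrom, mid, _cm, bp = parts[:4]
            markers.append(MarkerInfo(mid, chrom, int(bp)))
    individuals: list[str] = []
    rows: list[np.ndarray] = []
    # allele-1 per marker = first non-missing allele seen (arbitrary polarization)
    allele1: list[str | None] = [None] * len(markers)
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(markers):
                raise FormatError(
                    f"PED row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} fields, expected {6 + 2 * len(markers)}"
                )
            individuals.append(parts[1])
            row = np.full(len(markers), MISSING, dtype=np.int8)
            for j in range(len(markers)):
                a1, a2 = parts[6 + 2 * j], parts[7 + 2 * j]
                if a1 == "0" or a2 == "0":
                    continue
                if allele1[j] is None:
                    allele1[j] = a1
                code = int(a1 != allele1[j]) + int(a2 != allele1[j])
                row[j] = (HOM_A, HET, HOM_B)[code]
            rows.append(row)
    calls = (
        np.stack(rows, axis=0) if rows else np.empty((0, len(markers)), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, markers, calls)


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["marker_id", "chromosome", "position_bp"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"genotype TSV missing column {col!r}")
    has_info = "informative" in df.columns
    meta_cols = required + (["informative"] if has_info else [])
    ind_cols = [c for c in df.columns if c not in meta_cols]
    markers = [
        MarkerInfo(
            str(r.marker_id),
            str(r.chromosome),
            int(r.position_bp),
            informative=bool(int(r.informative)) if has_info else True,
        )
        for r in df.itertuples()
    ]
    calls = np.full((len(ind_cols), len(markers)), MISSING, dtype=np.int8)
    for j, r in enumerate(df[ind_cols].itertuples(index=False)):
        for i, cell in enumerate(r):
            try:
                calls[i, j] = _TSV_DECODE[str(cell)]
            except KeyError:
                raise FormatError(f"bad genotype cell {cell!r}") from None
    return GenotypeMatrix(ind_cols, markers, calls)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the one-row-per-marker TSV genotype dialect (cells A/H/B/-)."""
    with open(path, "w") as fh:
        fh.write(
            "\t".join(["marker_id", "chromosome", "position_bp", "informative"] + list(gm.individuals))
            + "\n"
        )
        for j, m in enumerate(gm.markers):
            cells = [_TSV_CODE[int(c)] for c in gm.calls[:, j]]
            fh.write(
                f"{m.marker_id}\t{m.chromosome}\t{m.position_bp}\t{int(m.informative)}\t"
                + "\t".join(cells)
                + "\n"
            )


def write_map(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a PLINK-style MAP file (chrom, id, cM=0, bp)."""
    with open(path, "w") as fh:
        for m in gm.markers:
            fh.write(f"{m.chromosome}\t{m.marker_id}\t0\t{m.position_bp}\n")


# ---------------------------------------------------------------------------
# pedigree readers / writers
# ---------------------------------------------------------------------------

_SEX_DECODE = {"1": "M", "2": "F", "0": "unknown", "M": "M", "F": "F", "unknown": "unknown"}


def read_pedigree(path: str | Path, format: str = "tsv") -> Pedigree:
    """Read a pedigree from a TSV (with explicit generations) or a PLINK FAM.

    FAM files carry no generation column; generations are assigned as the
    founder-distance depth (founders = 0, child = 1 + max parent depth).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("individual_id", "sire_id", "dam_id", "generation"):
            if col not in df.columns:
                raise FormatError(f"pedigree TSV missing column {col!r}")
        records = []
        for r in df.itertuples():
            sire = None if str(r.sire_id) in ("0", "-", "nan") else str(r.sire_id)
            dam = None if str(r.dam_id) in ("0", "-", "nan") else str(r.dam_id)
            sex = _SEX_DECODE.get(str(getattr(r, "sex", "unknown")), "unknown")
            records.append(
                PedigreeRecord(str(r.individual_id), sire, dam, int(r.generation), sex)
            )
        return Pedigree(records)
    if format == "fam":
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) < 5:
                    raise FormatError(f"FAM line with {len(parts)} fields")
                _fid, iid, pat, mat, sex = parts[:5]
                rows.append(
                    (
                        iid,
                        None if pat == "0" else pat,
                        None if mat == "0" else mat,
                        _SEX_DECODE.get(sex, "unknown"),
                    )
                )
        depth: dict[str, int] = {}

        def _depth(iid: str, seen: tuple[str, ...] = ()) -> int:
            if iid in seen:
                raise ValueError(f"pedigree cycle involving {iid!r}")
            if iid in depth:
                return depth[iid]
            parents = [p for row in rows if row[0] == iid for p in row[1:3] if p]
            d = 0 if not parents else 1 + max(_depth(p, seen + (iid,)) for p in parents)
            depth[iid] = d
            return d

        records = [
            PedigreeRecord(iid, sire, dam, _depth(iid), sex) for iid, sire, dam, sex in rows
        ]
        return Pedigree(records)
    raise FormatError(f"unknown pedigree format {format!r}")


def write_pedigree(ped: Pedigree, path: str | Path, format: str = "tsv") -> None:
    sex_code = {"M": "1", "F": "2", "unknown": "0"}
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write("individual_id\tsire_id\tdam_id\tgeneration\tsex\n")
            for r in ped.records:
                fh.write(
                    f"{r.individual_id}\t{r.sire_id or '-'}\t{r.dam_id or '-'}\t"
                    f"{r.generation}\t{r.sex}\n"
                )
        elif format == "fam":
            for r in ped.records:
                fh.write(
                    f"0\t{r.individual_id}\t{r.sire_id or '0'}\t{r.dam_id or '0'}\t"
                    f"{sex_code[r.sex]}\t-9\n"
                )
        else:
            raise FormatError(f"unknown pedigree format {format!r}")


# ---------------------------------------------------------------------------
# annotation / PPI readers
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV: gene_id, chromosome, start_bp, end_bp, biotype, nssnp_count."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "chromosome", "start_bp", "end_bp"):
        if col not in df.columns:
            raise FormatError(f"annotation TSV missing column {col!r}")
    return [
        GeneAnnotation(
            str(r.gene_id),
            str(r.chromosome),
            int(r.start_bp),
            int(r.end_bp),
            biotype=str(getattr(r, "biotype", "protein_coding")),
            nssnp_count=int(getattr(r, "nssnp_count", 0)),
        )
        for r in df.itertuples()
    ]


def read_ppi_edges(path: str | Path) -> list[PpiEdge]:
    """Read a PPI edge TSV: gene_a, gene_b, score."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    edges = []
    for r in df.itertuples():
        edges.append(PpiEdge(str(r.gene_a), str(r.gene_b), float(getattr(r, "score", 0.0))))
    return edges


# ---------------------------------------------------------------------------
# region writer (Table-1-style TSV / BED)
# ---------------------------------------------------------------------------

REGION_TSV_COLUMNS = [
    "region_id",
    "chromosome",
    "proximal_bp",
    "top_bp",
    "distal_bp",
    "size_bp",
    "n_snps",
    "preferred_allele",
    "mean_n_A",
    "sd_n_A",
    "mean_n_B",
    "sd_n_B",
    "top_marker_id",
    "top_n_A",
    "top_n_B",
    "distortion_percent",
]


def write_regions(regions: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write TRD regions as a Table-1-style TSV or a BED file.

    The TSV mirrors the published region-table layout: interval bounds, top
    marker, per-region transmission means +/- SD, and signed distortion
    percent at the top marker.  BED output converts the 1-based inclusive
    internal interval to 0-based half-open.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(REGION_TSV_COLUMNS) + "\n")
            for r in regions:
                fh.write(
                    "\t".join(
                        [
                            r.region_id,
                            r.chromosome,
                            str(r.proximal_bp),
                            str(r.top_bp),
                            str(r.distal_bp),
                            str(r.distal_bp - r.proximal_bp),
                            str(r.n_snps),
                            r.preferred_allele,
                            f"{r.mean_n_A:.1f}",
                            f"{r.sd_n_A:.1f}",
                            f"{r.mean_n_B:.1f}",
                            f"{r.sd_n_B:.1f}",
                            r.top_marker_id,
                            str(r.top_n_A),
                            str(r.top_n_B),
                            f"{r.distortion_percent:.1f}",
                        ]
                    )
                    + "\n"
                )
    elif format == "bed":
        with open(path, "w") as fh:
            for r in regions:
                fh.write(f"{r.chromosome}\t{r.proximal_bp - 1}\t{r.distal_bp}\t{r.region_id}\n")
    else:
        raise FormatError(f"unknown region format {format!r}")
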