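"""Forward-in-time simulator for a two-founder advanced intercross line (AIL).

Two fully inbred founders carrying opposite alleles at every marker are
crossed to an F1, and each following generation is produced by random
non-sibling pairings with litter-structured offspring.  Meiosis samples
crossovers under a no-interference (Haldane) model on the centimorgan map
(1 cM = 1% recombination).  Two distortion mechanisms can be injected with
known ground truth:

* gamete-level drive: a heterozygous carrier at a driver locus transmits
  the founder-A allele with probability tau instead of 1/2, optionally
  restricted to one parental sex (expected marker-level distortion is
  100*(2*tau - 1) percent);
* two-locus viability selection: each conceived offspring survives with
  probability given by a 3x3 viability matrix over its joint genotype
  classes at an unlinked marker pair, the forward model of a
  Bateson-Dobzhansky-Muller incompatibility.

Output is a founder-polarized GenotypeMatrix over all simulated
individuals, a full Pedigree, and the injected ground truth, so every
downstream scan can be validated against known parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    MISSING,
    GenotypeMatrix,
    MarkerInfo,
    Pedigree,
    PedigreeRecord,
)


class SimulationError(RuntimeError):
    """Raised when the simulated population dies out."""


@dataclass
class SimulationConfig:
    """Population and map parameters of the simulated AIL.

    ``generations`` counts intercross generations: founders are generation
    0, the F1 generation 1, and random mating fills generations 2 through
    ``generations``.  ``final_families``/``final_litter_size`` optionally
    enlarge the last generation only, the one a transmission scan samples
    trios from.
    """

    n_chromosomes: int = 5
    markers_per_chromosome: int = 200
    chromosome_length_cM: float = 100.0
    generations: int = 10
    families_per_generation: int = 30
    litter_size: int = 4
    genotype_missing_rate: float = 0.0
    seed: int = 0
    bp_per_cM: int = 2_000_000
    final_families: int | None = None
    final_litter_size: int | None = None

    def __post_init__(self):
        for name in (
            "n_chromosomes",
            "markers_per_chromosome",
            "generations",
            "families_per_generation",
            "litter_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.genotype_missing_rate <= 1:
            raise ValueError("genotype_missing_rate must be in [0,1]")
        if self.chromosome_length_cM <= 0:
            raise ValueError("chromosome_length_cM must be positive")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


@dataclass
class DriverLocus:
    """A meiotic-drive locus: heterozygotes transmit allele A with probability tau."""

    marker_index: int
    tau: float
    sex_restricted: str = "both"  # {"paternal", "maternal", "both"}

    def __post_init__(self):
        if not 0 <= self.tau <= 1:
            raise ValueError("tau must be in [0,1]")
        if self.sex_restricted not in ("paternal", "maternal", "both"):
            raise ValueError("sex_restricted must be paternal/maternal/both")


@dataclass
class IncompatPair:
    """Two-locus viability selection over joint genotype classes.

    ``viability[i, j]`` is the survival probability of an offspring with
    genotype class i (0=HOM_A, 1=HET, 2=HOM_B) at the first marker and j at
    the second.  An all-ones matrix is neutral.
    """

    marker_index_1: int
    marker_index_2: int
    viability: np.ndarray

    def __post_init__(self):
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.shape != (3, 3):
            raise ValueError("viability must be 3x3")
        if ((self.viability < 0) | (self.viability > 1)).any():
            raise ValueError("viability entries must be in [0,1]")

    def minimal_cells(self) -> list[tuple[int, int]]:
        vmin = self.viability.min()
        return [tuple(ix) for ix in np.argwhere(self.viability == vmin)]


@dataclass
class GroundTruth:
    """Injected distortion parameters, for validating downstream scans."""

    driver_expected_distortion: dict[int, float] = field(default_factory=dict)
    incompatibility_cells: list[dict] = field(default_factory=list)


def expected_distortion(tau: float) -> float:
    """Closed-form marker-level distortion percent under drive: 100*(2*tau-1)."""
    if not 0 <= tau <= 1:
        raise ValueError("tau must be in [0,1]")
    return 100.0 * (2.0 * tau - 1.0)


class _AilEngine:
    """Internal state of one simulation run."""

    MAX_GAMETE_RETRIES = 100
    MAX_OFFSPRING_RETRIES = 100

    def __init__(self, config, drivers, incompatibilities, rng):
        self.cfg = config
        self.rng = rng
        self.drivers = drivers
        self.incompat = incompatibilities
        n = config.n_markers
        for d in drivers:
            if not 0 <= d.marker_index < n:
                raise ValueError(f"driver marker index {d.marker_index} out of range")
        for p in incompatibilities:
            if not (0 <= p.marker_index_1 < n and 0 <= p.marker_index_2 < n):
                raise ValueError("incompatibility marker index out of range")
        m = config.markers_per_chromosome
        self.chrom_slices = [slice(c * m, (c + 1) * m) for c in range(config.n_chromosomes)]
        # evenly spaced marker positions on the cM map, half-step offset from 0
        step = config.chromosome_length_cM / m
        self.cm_positions = (np.arange(m) + 0.5) * step
        self.hap1: dict[str, np.ndarray] = {}
        self.hap2: dict[str, np.ndarray] = {}
        self.sex: dict[str, str] = {}
        self.records: list[PedigreeRecord] = []

    # -- meiosis -----------------------------------------------------------
    def _gamete(self, iid: str) -> np.ndarray:
        h1, h2, cfg = self.hap1[iid], self.hap2[iid], self.cfg
        g = np.empty(cfg.n_markers, dtype=np.int8)
        L = cfg.chromosome_length_cM
        for sl in self.chrom_slices:
            k = self.rng.poisson(L / 100.0)
            start = int(self.rng.integers(2))
            if k == 0:
                phase = np.full(len(self.cm_positions), start)
            else:
                xs = np.sort(self.rng.uniform(0.0, L, size=k))
                phase = (start + np.searchsorted(xs, self.cm_positions)) % 2
            g[sl] = np.where(phase == 0, h1[sl], h2[sl])
        return g

    def _gamete_with_drive(self, iid: str, parent_role: str) -> np.ndarray:
        active = [
            d
            for d in self.drivers
            if d.sex_restricted in ("both", parent_role)
            and self.hap1[iid][d.marker_index] != self.hap2[iid][d.marker_index]
        ]
        if not active:
            return self._gamete(iid)
        # rejection sampling normalized by the per-driver maximum so the
        # marginal transmission probability of allele A is exactly tau
        norm = np.prod([max(d.tau, 1.0 - d.tau) for d in active])
        g = self._gamete(iid)
        for _ in range(self.MAX_GAMETE_RETRIES):
            accept = np.prod(
                [d.tau if g[d.marker_index] == 0 else 1.0 - d.tau for d in active]
            )
            if self.rng.random() < accept / norm:
                return g
            g = self._gamete(iid)
        return g

    # -- offspring ---------------------------------------------------------
    def _survival(self, hs: np.ndarray, hd: np.ndarray) -> float:
        v = 1.0
        for pair in self.incompat:
            g1 = int(hs[pair.marker_index_1] + hd[pair.marker_index_1])
            g2 = int(hs[pair.marker_index_2] + hd[pair.marker_index_2])
            v *= pair.viability[g1, g2]
        return v

    def _make_child(self, iid, sire, dam, generation):
        for _ in range(self.MAX_OFFSPRING_RETRIES):
            hs = self._gamete_with_drive(sire, "paternal")
            hd = self._gamete_with_drive(dam, "maternal")
            if not self.incompat or self.rng.random() < self._survival(hs, hd):
                self.hap1[iid] = hs
                self.hap2[iid] = hd
                sex = "M" if self.rng.random() < 0.5 else "F"
                self.sex[iid] = sex
                self.records.append(PedigreeRecord(iid, sire, dam, generation, sex))
                return True
        return False  # litter slot lost to selection

    def _add_founder(self, iid: str, allele: int, sex: str):
        n = self.cfg.n_markers
        self.hap1[iid] = np.full(n, allele, dtype=np.int8)
        self.hap2[iid] = np.full(n, allele, dtype=np.int8)
        self.sex[iid] = sex
        self.records.append(PedigreeRecord(iid, None, None, 0, sex))

    # -- mating ------------------------------------------------------------
    def _pairs(self, members: list[str], n_families: int) -> list[tuple[str, str]]:
        males = [i for i in members if self.sex[i] == "M"]
        females = [i for i in members if self.sex[i] == "F"]
        if not males or not females:
            raise SimulationError("population extinct: a generation lacks one sex")
        self.rng.shuffle(males)
        self.rng.shuffle(females)
        parents = {r.individual_id: (r.sire_id, r.dam_id) for r in self.records}
        pairs: list[tuple[str, str]] = []
        fi = 0
        for k in range(n_families):
            male = males[k % len(males)]
            # best-effort full-sib avoidance: scan for a non-sib female
            chosen = None
            for off in range(len(females)):
                cand = females[(fi + off) % len(females)]
                if parents[cand] != parents[male] or parents[male] == (None, None):
                    chosen = cand
                    fi = (fi + off + 1) % len(females)
                    break
            if chosen is None:  # everyone is a full sib; mate anyway
                chosen = females[fi % len(females)]
                fi += 1
            pairs.append((male, chosen))
        return pairs

    # -- main loop ---------------------------------------------------------
    def run(self):
        cfg = self.cfg
        self._add_founder("FOUNDER_A", 0, "M")
        self._add_founder("FOUNDER_B", 1, "F")
        current = []
        n_f1 = cfg.families_per_generation * cfg.litter_size
        for i in range(n_f1):
            iid = f"G1_{i}"
            if self._make_child(iid, "FOUNDER_A", "FOUNDER_B", 1):
                current.append(iid)
        if not current:
            raise SimulationError("population extinct in the F1")
        for gen in range(2, cfg.generations + 1):
            last = gen == cfg.generations
            n_fam = cfg.final_families if (last and cfg.final_families) else cfg.families_per_generation
            litter = cfg.final_litter_size if (last and cfg.final_litter_size) else cfg.litter_size
            pairs = self._pairs(current, n_fam)
            nxt = []
            for k, (sire, dam) in enumerate(pairs):
                for c in range(litter):
                    iid = f"G{gen}_{k}_{c}"
                    if self._make_child(iid, sire, dam, gen):
                        nxt.append(iid)
            if not nxt:
                raise SimulationError(f"population extinct in generation {gen}")
            current = nxt

    # -- outputs -----------------------------------------------------------
    def genotype_matrix(self) -> GenotypeMatrix:
        cfg = self.cfg
        ids = [r.individual_id for r in self.records]
        calls = np.empty((len(ids), cfg.n_markers), dtype=np.int8)
        for i, iid in enumerate(ids):
            calls[i] = self.hap1[iid] + self.hap2[iid]  # 0/1/2 = HOM_A/HET/HOM_B
        if cfg.genotype_missing_rate > 0:
            mask = self.rng.random(calls.shape) < cfg.genotype_missing_rate
            calls[mask] = MISSING
        markers = []
        step = cfg.chromosome_length_cM / cfg.markers_per_chromosome
        for c in range(cfg.n_chromosomes):
            for m in range(cfg.markers_per_chromosome):
                cm = (m + 0.5) * step
                markers.append(
                    MarkerInfo(
                        marker_id=f"chr{c + 1}_m{m + 1}",
                        chromosome=str(c + 1),
                        position_bp=int(round(cm * cfg.bp_per_cM)) + 1,
                        informative=True,
                    )
                )
        return GenotypeMatrix(ids, markers, calls)


def simulate_ail(
    config: SimulationConfig,
    drivers: list[DriverLocus] | None = None,
    incompatibilities: list[IncompatPair] | None = None,
) -> tuple[GenotypeMatrix, Pedigree, GroundTruth]:
    """Run the forward simulation; deterministic given config (incl. seed)."""
    drivers = drivers or []
    incompatibilities = incompatibilities or []
    rng = np.random.default_rng(config.seed)
    engine = _AilEngine(config, drivers, incompatibilities, rng)
    engine.run()
    genotypes = engine.genotype_matrix()
    pedigree = Pedigree(list(engine.records))
    truth = GroundTruth(
        driver_expected_distortion={
            d.marker_index: expected_distortion(d.tau) for d in drivers
        },
        incompatibility_cells=[
            {
                "marker_index_1": p.marker_index_1,
                "marker_index_2": p.marker_index_2,
                "min_viability": float(p.viability.min()),
                "cells": p.minimal_cells(),
            }
            for p in incompatibilities
        ],
    )
    return genotypes, pedigree, truth
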