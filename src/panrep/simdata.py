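"""Synthetic biopanning: ground-truth VHH libraries, multi-round selection,
and paired-read emission.

The generator emulates an in-vivo phage-display experiment: a naive VHH
library (CDR3 lengths with median 18 aa, range 1-36) is carried through
successive biopanning rounds.  Each round, phage are captured on sorted
immune-cell subtypes; capture is a multinomial draw weighted by clone
frequency times subtype affinity, and the bulk-leukocyte (CD45) capture,
after noisy amplification, seeds the next round.  Planted binders carry a
lognormal affinity multiplier for one subtype (and for the bulk pool, since
their target cells sit inside it); everything else selects neutrally.

All randomness flows from a single integer seed; per-sample substreams are
derived deterministically from (seed, replicate, round, subtype), so outputs
are byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .amplicon import FLANK_3P, FLANK_5P, DEFAULT_SCAFFOLD, Read, Scaffold, revcomp
from .repertoire import BULK_SUBTYPE, CELL_SUBTYPES, SUBTYPE_ROSTER

__all__ = [
    "SimulationConfig",
    "TrueClone",
    "SimulatedSample",
    "BiopanningSimulation",
    "generate_library",
    "simulate_round",
    "simulate_biopanning",
    "emit_reads",
    "sample_id",
    "recovery_scenario",
]

# CDR residue alphabet: the 20 standard amino acids minus cysteine, so CDR
# loops never introduce unpaired cysteines that shadow the framework anchors.
CDR_ALPHABET = "ADEFGHIKLMNPQRSTVWY"

_CODONS_BY_AA: dict[str, list[str]] = {}


def _codons_by_aa() -> dict[str, list[str]]:
    global _CODONS_BY_AA
    if not _CODONS_BY_AA:
        from Bio.Data.CodonTable import standard_dna_table

        by_aa: dict[str, list[str]] = {}
        for codon, aa in sorted(standard_dna_table.forward_table.items()):
            by_aa.setdefault(aa, []).append(codon)
        _CODONS_BY_AA = by_aa
    return _CODONS_BY_AA


def default_cdr3_length_law(mean: float = 18.0, sd: float = 4.0) -> np.ndarray:
    """Discretized-normal pmf over CDR3 lengths 1..36 aa.

    Calibrated so the distribution's median is 18 aa with support 1-36,
    matching the naive-library CDR3 length profile.
    """
    k = np.arange(1, 37, dtype=float)
    w = np.exp(-((k - mean) ** 2) / (2.0 * sd * sd))
    return w / w.sum()


@dataclass
class SimulationConfig:
    """All generator parameters; ``seed`` is required.

    ``capture_range`` is the in-vivo per-subtype phage yield (4e6-6e7); the
    simulator draws the capture size uniformly in that range scaled by
    ``capture_scale``.  ``reads_per_sample`` scales the study's ~450,000
    reads per sample to desk size.  ``seq_error_rate`` is the effective
    per-base substitution rate of a merged, quality-filtered amplicon.
    """

    seed: int
    n_clones: int = 5000
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    cdr3_length_probs: Optional[np.ndarray] = None  # pmf over lengths 1..36
    cdr1_length_range: tuple[int, int] = (5, 8)
    cdr2_length_range: tuple[int, int] = (6, 9)
    n_binders_per_subtype: int = 20
    binder_affinity_mu: float = math.log(8.0)
    binder_affinity_sigma: float = 0.3
    background_affinity: float = 1.0
    binder_rarity: float = 0.02
    shared_binders: bool = False
    amplification_noise_sd: float = 0.3
    capture_range: tuple[float, float] = (4e6, 6e7)
    capture_scale: float = 1e-3
    reads_per_sample: int = 4500
    read_length: int = 300
    seq_error_rate: float = 1e-4
    n_rounds: int = 4
    n_replicates: int = 3
    scaffold: Scaffold = field(default_factory=lambda: DEFAULT_SCAFFOLD)

    def __post_init__(self) -> None:
        if self.cdr3_length_probs is None:
            self.cdr3_length_probs = default_cdr3_length_law()
        p = np.asarray(self.cdr3_length_probs, dtype=float)
        if p.shape != (36,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("cdr3_length_probs must be a pmf over lengths 1..36")
        self.cdr3_length_probs = p
        if self.n_clones < 1:
            raise ValueError("n_clones must be positive")
        if not self.shared_binders and self.n_binders_per_subtype * len(CELL_SUBTYPES) > self.n_clones:
            raise ValueError(
                "n_binders_per_subtype x 5 exceeds n_clones with disjoint binder sets"
            )
        for name in ("cdr1_length_range", "cdr2_length_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid {name}")
        if self.background_affinity <= 0:
            raise ValueError("background_affinity must be positive")
        if not 0.0 < self.binder_rarity <= 1.0:
            raise ValueError("binder_rarity must be in (0, 1]")
        if self.amplification_noise_sd < 0:
            raise ValueError("amplification_noise_sd must be nonnegative")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must be in [0, 1)")
        if self.reads_per_sample < 0 or self.read_length < 1:
            raise ValueError("invalid read configuration")
        if self.n_rounds < 1 or self.n_replicates < 1:
            raise ValueError("n_rounds and n_replicates must be positive")

    def capture_size(self, rng: np.random.Generator) -> int:
        lo, hi = self.capture_range
        size = int(round(rng.uniform(lo, hi) * self.capture_scale))
        return max(size, 1)

    @property
    def phred_char(self) -> str:
        e = self.seq_error_rate
        q = 40 if e <= 0 else min(40, int(round(-10.0 * math.log10(e))))
        return chr(q + 33)


@dataclass
class TrueClone:
    """Ground-truth library member."""

    clone_id: str
    cdr1_aa: str
    cdr2_aa: str
    cdr3_aa: str
    nt_cds: str
    initial_frequency: float
    affinity: dict[str, float] = field(default_factory=dict)  # only non-background

    def affinity_for(self, subtype: str, background: float = 1.0) -> float:
        return self.affinity.get(subtype, background)

    def aa_sequence(self, scaffold: Scaffold = DEFAULT_SCAFFOLD) -> str:
        return (
            scaffold.fr1 + self.cdr1_aa + scaffold.fr2 + self.cdr2_aa
            + scaffold.fr3 + self.cdr3_aa + scaffold.fr4
        )

    @property
    def target_subtype(self) -> Optional[str]:
        for s in CELL_SUBTYPES:
            if s in self.affinity:
                return s
        return None


def _encode(aa: str, rng: np.random.Generator) -> str:
    """Nucleotide encoding with a uniform choice among synonymous codons."""
    by_aa = _codons_by_aa()
    return "".join(by_aa[a][rng.integers(len(by_aa[a]))] for a in aa)


def generate_library(config: SimulationConfig) -> list[TrueClone]:
    """Draw the naive library: CDR sequences, codon usage, initial
    frequencies (lognormal, normalized to 1) and planted binder affinities."""
    rng = np.random.default_rng([config.seed, 0])
    sc = config.scaffold
    n = config.n_clones

    lens3 = rng.choice(np.arange(1, 37), size=n, p=config.cdr3_length_probs)
    lens1 = rng.integers(config.cdr1_length_range[0], config.cdr1_length_range[1] + 1, size=n)
    lens2 = rng.integers(config.cdr2_length_range[0], config.cdr2_length_range[1] + 1, size=n)

    seen: set[str] = set()
    clones: list[TrueClone] = []
    width = max(5, len(str(n)))
    for i in range(n):
        for _attempt in range(100):
            c1 = "".join(rng.choice(list(CDR_ALPHABET), lens1[i]))
            c2 = "".join(rng.choice(list(CDR_ALPHABET), lens2[i]))
            c3 = "".join(rng.choice(list(CDR_ALPHABET), lens3[i]))
            aa = sc.fr1 + c1 + sc.fr2 + c2 + sc.fr3 + c3 + sc.fr4
            nt = _encode(aa, rng)
            if nt not in seen:
                break
        seen.add(nt)
        clones.append(
            TrueClone(
                clone_id=f"c{i:0{width}d}",
                cdr1_aa=c1, cdr2_aa=c2, cdr3_aa=c3,
                nt_cds=nt, initial_frequency=0.0,
            )
        )

    k = config.n_binders_per_subtype
    if k:
        if config.shared_binders:
            for s in CELL_SUBTYPES:
                picks = rng.choice(n, size=k, replace=False)
                for j in picks:
                    kappa = float(rng.lognormal(config.binder_affinity_mu, config.binder_affinity_sigma))
                    clones[j].affinity[s] = kappa
                    clones[j].affinity[BULK_SUBTYPE] = max(
                        clones[j].affinity.get(BULK_SUBTYPE, 0.0), kappa
                    )
        else:
            perm = rng.permutation(n)
            for si, s in enumerate(CELL_SUBTYPES):
                for j in perm[si * k : (si + 1) * k]:
                    kappa = float(rng.lognormal(config.binder_affinity_mu, config.binder_affinity_sigma))
                    clones[j].affinity[s] = kappa
                    clones[j].affinity[BULK_SUBTYPE] = kappa

    # Binders in the real library are individually rare (any specific clone
    # in a ~2e9-member library sits far below the mean frequency); at desk
    # scale that rarity is preserved by scaling binder initial frequencies
    # by `binder_rarity` before normalization, so the selection dynamics
    # (saturation in the late rounds, not before BP2) match the experiment.
    freqs = rng.lognormal(config.abundance_mu, config.abundance_sigma, size=n)
    for i, clone in enumerate(clones):
        if clone.affinity:
            freqs[i] *= config.binder_rarity
    freqs /= freqs.sum()
    for clone, f in zip(clones, freqs):
        clone.initial_frequency = float(f)
    return clones


def binder_ids(library: Sequence[TrueClone]) -> dict[str, list[str]]:
    """Planted binder clone ids per target subtype."""
    out: dict[str, list[str]] = {s: [] for s in CELL_SUBTYPES}
    for clone in library:
        for s in CELL_SUBTYPES:
            if s in clone.affinity:
                out[s].append(clone.clone_id)
    return out


def affinity_vector(
    library: Sequence[TrueClone], subtype: str, background: float = 1.0
) -> np.ndarray:
    return np.array([c.affinity_for(subtype, background) for c in library])


# ---------------------------------------------------------------------------
# Selection dynamics
# ---------------------------------------------------------------------------


def simulate_round(
    freqs: np.ndarray,
    affinity: np.ndarray,
    capture_size: int,
    amplification_noise_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One capture + amplification step for one subtype.

    Capture is a multinomial draw of ``capture_size`` phage with per-clone
    probability proportional to frequency x affinity; amplification perturbs
    each captured count by a multiplicative lognormal factor and
    renormalizes.  Returns (captured counts, amplified frequency vector).
    """
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("input frequencies must sum to 1")
    w = freqs * np.asarray(affinity, dtype=float)
    p = w / w.sum()
    captured = rng.multinomial(capture_size, p)
    amplified = captured.astype(float)
    if amplification_noise_sd > 0:
        amplified = amplified * np.exp(rng.normal(0.0, amplification_noise_sd, size=len(amplified)))
    total = amplified.sum()
    if total == 0:
        raise RuntimeError("amplification produced an empty pool")
    return captured, amplified / total


def sample_id(round_: int, subtype: str, replicate: int) -> str:
    return f"BP{round_}_{subtype}_rep{replicate}"


def _sub_rng(config: SimulationConfig, replicate: int, round_: int, subtype: str, salt: int) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, 1 + salt, replicate, round_, SUBTYPE_ROSTER.index(subtype)]
    )


@dataclass
class SimulatedSample:
    """Truth for one sequenced sample (one capture)."""

    round: int
    subtype: str
    replicate: int
    capture_size: int
    capture_probs: np.ndarray  # expected post-selection frequencies
    captured: np.ndarray  # realized capture counts
    read_counts: Optional[np.ndarray] = None  # realized sequenced reads per clone

    @property
    def id(self) -> str:
        return sample_id(self.round, self.subtype, self.replicate)

    @property
    def proportions(self) -> np.ndarray:
        return self.captured / self.captured.sum()


@dataclass
class BiopanningSimulation:
    """Full simulated experiment: library plus per-sample truth."""

    config: SimulationConfig
    library: list[TrueClone]
    samples: dict[tuple[int, str, int], SimulatedSample]

    def sample(self, round_: int, subtype: str, replicate: int = 0) -> SimulatedSample:
        return self.samples[(round_, subtype, replicate)]

    def truth_frame(self) -> pd.DataFrame:
        """Tidy truth table: one row per (clone, sample) with nonzero signal."""
        ids = np.array([c.clone_id for c in self.library])
        rows = []
        for (r, s, rep), smp in sorted(self.samples.items()):
            reads = smp.read_counts if smp.read_counts is not None else np.zeros(len(ids), dtype=int)
            mask = (smp.captured > 0) | (reads > 0)
            for i in np.nonzero(mask)[0]:
                rows.append(
                    (ids[i], r, s, rep, float(smp.capture_probs[i]), int(smp.captured[i]), int(reads[i]))
                )
        return pd.DataFrame(
            rows, columns=["clone_id", "round", "subtype", "replicate", "true_freq", "captured", "reads"]
        )


def simulate_biopanning(
    config: SimulationConfig, library: Optional[Sequence[TrueClone]] = None
) -> BiopanningSimulation:
    """Run the full selection: BP0 bulk capture, then ``n_rounds`` rounds of
    per-subtype capture, each round seeded by the previous round's amplified
    bulk (CD45) pool.  Subtype streams are measurements, not lineages."""
    library = list(library) if library is not None else generate_library(config)
    aff = {s: affinity_vector(library, s, config.background_affinity) for s in SUBTYPE_ROSTER}
    init = np.array([c.initial_frequency for c in library])
    samples: dict[tuple[int, str, int], SimulatedSample] = {}

    for rep in range(config.n_replicates):
        rng0 = _sub_rng(config, rep, 0, BULK_SUBTYPE, 0)
        size0 = config.capture_size(rng0)
        captured, pool = simulate_round(
            init, aff[BULK_SUBTYPE], size0, config.amplification_noise_sd, rng0
        )
        w0 = init * aff[BULK_SUBTYPE]
        samples[(0, BULK_SUBTYPE, rep)] = SimulatedSample(0, BULK_SUBTYPE, rep, size0, w0 / w0.sum(), captured)

        for r in range(1, config.n_rounds + 1):
            next_pool = pool
            for s in SUBTYPE_ROSTER:
                rng = _sub_rng(config, rep, r, s, 0)
                size = config.capture_size(rng)
                captured, amplified = simulate_round(
                    pool, aff[s], size, config.amplification_noise_sd, rng
                )
                w = pool * aff[s]
                samples[(r, s, rep)] = SimulatedSample(r, s, rep, size, w / w.sum(), captured)
                if s == BULK_SUBTYPE:
                    next_pool = amplified
            pool = next_pool

    return BiopanningSimulation(config, library, samples)


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: str, n_err: int, rng: np.random.Generator) -> str:
    if n_err == 0:
        return seq
    arr = bytearray(seq, "ascii")
    pos = rng.choice(len(arr), size=min(n_err, len(arr)), replace=False)
    for p in pos:
        old = arr[p]
        new = old
        while new == old:
            new = int(_BASES[rng.integers(4)])
        arr[p] = new
    return arr.decode("ascii")


def emit_reads(
    counts: np.ndarray,
    library: Sequence[TrueClone],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[Read, Read]], np.ndarray]:
    """Sequence a sample: draw ``reads_per_sample`` amplicons in proportion to
    the capture counts and emit paired reads with substitution errors.

    Read 1 is the first ``read_length`` bases of the amplicon, read 2 the
    reverse complement of the last ``read_length`` bases; Phred strings
    encode the configured error rate.  Returns the pairs and the realized
    per-clone read counts (which sum to ``reads_per_sample``).
    """
    counts = np.asarray(counts)
    L = config.read_length
    n_reads = config.reads_per_sample
    read_counts = np.zeros(len(library), dtype=int)
    if n_reads == 0:
        return [], read_counts
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot sequence a sample with zero captured phage")

    amplicons = [FLANK_5P + c.nt_cds + FLANK_3P for c in library]
    min_amp = min(len(a) for a in amplicons)
    if min_amp < L:
        raise ValueError(
            f"shortest amplicon ({min_amp} nt) is shorter than the read length {L}"
        )

    read_counts = rng.multinomial(n_reads, counts / total)
    clone_idx = np.repeat(np.arange(len(library)), read_counts)
    rng.shuffle(clone_idx)
    n_err = rng.binomial(L, config.seq_error_rate, size=(n_reads, 2))
    qual = config.phred_char * L

    pairs: list[tuple[Read, Read]] = []
    for i, ci in enumerate(clone_idx):
        amp = amplicons[ci]
        r1 = _mutate(amp[:L], int(n_err[i, 0]), rng)
        r2 = _mutate(revcomp(amp[-L:]), int(n_err[i, 1]), rng)
        rid = f"read{i}"
        pairs.append((Read(rid, r1, qual), Read(rid, r2, qual)))
    return pairs, read_counts


def emit_sample_reads(
    sim: BiopanningSimulation, round_: int, subtype: str, replicate: int
) -> list[tuple[Read, Read]]:
    """Emit reads for one simulated sample, updating its truth read counts.

    The per-sample substream makes emission deterministic and independent of
    the order in which samples are sequenced.
    """
    smp = sim.sample(round_, subtype, replicate)
    rng = _sub_rng(sim.config, replicate, round_, subtype, 1)
    sid = smp.id
    pairs, read_counts = emit_reads(smp.captured, sim.library, sim.config, rng)
    smp.read_counts = read_counts
    return [
        (Read(f"{sid}|{p1.id}", p1.seq, p1.qual), Read(f"{sid}|{p2.id}", p2.seq, p2.qual))
        for p1, p2 in pairs
    ]


def recovery_scenario(seed: int) -> SimulationConfig:
    """Desk-scale end-to-end scenario used for binder-recovery evaluation:
    1,000 clones, 10 planted binders per subtype, 3 replicate mice, 4,500
    read pairs per sample.  The capture scale is raised to 1e-2 so that the
    per-clone captured copy number (~40-600) does not extinguish average
    clones at this library size; founder loss then affects only the rare
    tail, as in the full-scale experiment."""
    return SimulationConfig(
        seed=seed,
        n_clones=1000,
        n_binders_per_subtype=10,
        reads_per_sample=4500,
        n_replicates=3,
        capture_scale=1e-2,
    )
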