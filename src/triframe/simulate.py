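"""Synthetic protein families and error-prone long-read simulation.

This module builds desk-scale datasets with the statistical structure the
classifier assumes: families of homologous proteins that share planted
conserved motifs (the discriminative signal), reverse-translated to coding
sequences, then sampled as reads with configurable per-base substitution/
insertion/deletion errors in the style of long-read simulators. Outlier
reads — reads carrying none of the trained motifs — are generated either as
uniform random DNA or from independent "decoy" families, guaranteed
motif-disjoint from the in-distribution families.

Errors are applied i.i.d. per base. Real instrument error models are more
structured (homopolymer bias, quality dependence), but the i.i.d. model is
exactly calibratable, which is what the method's properties need.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .alphabet import AA_TO_CODONS, AMINO_ACIDS
from .encoding import reverse_complement

#: Sentinel label for reads that carry no trained domain family.
OUTLIER = -1

#: Default substitution : insertion : deletion mix, the published CLR
#: default of the PBSIM long-read simulator.
DEFAULT_ERROR_RATIO = (0.10, 0.60, 0.30)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FamilySpec:
    """Blueprint for a set of synthetic protein families.

    Each family is defined by a random consensus protein carrying
    ``motifs_per_family`` planted motifs of ``motif_length`` residues at
    non-overlapping positions. Members copy the consensus exactly inside
    motifs and substitute each non-motif residue independently with
    probability ``within_family_substitution_rate``.
    """

    n_families: int = 5
    protein_length: int = 120
    motifs_per_family: int = 1
    motif_length: int = 12
    within_family_substitution_rate: float = 0.10
    members_per_family: int = 24
    shared_background: bool = True
    motif_margin: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 2:
            raise ValueError("n_families must be >= 2")
        if self.motif_margin < 0:
            raise ValueError("motif_margin must be >= 0")
        span = self.protein_length - 2 * self.motif_margin
        if self.motif_length * self.motifs_per_family > span:
            raise ValueError(
                "motif placement would overlap: motifs do not fit in the "
                "interior span of the protein"
            )
        if not 0.0 <= self.within_family_substitution_rate <= 1.0:
            raise ValueError("substitution rate must be a probability")
        if self.members_per_family < 1:
            raise ValueError("members_per_family must be >= 1")


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation settings.

    error_rate
        Per-base probability that a base is hit by an error.
    error_ratio
        (substitution, insertion, deletion) mix; must sum to 1.
    coverage
        Fold coverage per reference (sum of read lengths / reference length).
    read_length_model
        ``None`` for full-length reads, else ``(mean, sd)`` of a log-normal
        read-length distribution in nucleotides.
    strand
        ``"plus"`` or ``"both"``; with ``"both"`` every other read is
        reverse-complemented.
    """

    error_rate: float = 0.10
    error_ratio: tuple[float, float, float] = DEFAULT_ERROR_RATIO
    coverage: float = 80.0
    read_length_model: tuple[float, float] | None = None
    strand: str = "plus"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must be in [0, 0.2]")
        if min(self.error_ratio) < 0 or abs(sum(self.error_ratio) - 1.0) > 1e-9:
            raise ValueError("error_ratio must be non-negative and sum to 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.strand not in ("plus", "both"):
            raise ValueError("strand must be 'plus' or 'both'")


@dataclass
class DnaRead:
    read_id: str
    sequence: str
    true_label: int  # family index, or OUTLIER
    source_frame_offset: int = 0


@dataclass
class LabeledDataset:
    reads: list[DnaRead]
    label_names: list[str]

    def __post_init__(self) -> None:
        n = len(self.label_names)
        for r in self.reads:
            if r.true_label != OUTLIER and not 0 <= r.true_label < n:
                raise ValueError(f"label {r.true_label} outside label_names")

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.reads]

    def labels(self) -> np.ndarray:
        return np.array([r.true_label for r in self.reads], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class ProteinFamilies:
    """Labeled reference proteins produced by :func:`generate_families`."""

    label_names: list[str]
    consensus: list[str]
    motifs: list[list[tuple[int, str]]]  # per family: (start, motif string)
    members: list[list[str]]
    spec: FamilySpec

    def motif_strings(self) -> list[str]:
        return [m for fam in self.motifs for _, m in fam]


@dataclass
class ReferenceSet:
    """Labeled coding sequences ready for read simulation."""

    sequences: list[str]
    labels: list[int]
    label_names: list[str]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _place_motifs(
    rng: np.random.Generator,
    protein_length: int,
    k: int,
    m: int,
    margin: int,
) -> list[int]:
    """Random non-overlapping motif starts in the protein's interior.

    The margin keeps motifs away from the termini so that reads shorter
    than the full coding sequence still cover them.
    """
    slack = protein_length - 2 * margin - k * m
    if slack < 0:
        raise ValueError("motif placement would overlap: motifs exceed protein")
    gaps = np.sort(rng.integers(0, slack + 1, size=k))
    return [int(margin + gaps[i] + i * m) for i in range(k)]


def generate_families(spec: FamilySpec) -> ProteinFamilies:
    """Generate labeled families of homologous proteins with planted motifs.

    With ``shared_background`` (the default) one background protein is drawn
    and every family plants its motifs into it, so the planted motifs are
    the only family-discriminative signal — the ground truth for both the
    classifier and filter interpretation. Without it each family also gets
    its own random background. Deterministic given ``spec.seed``; motif
    strings are distinct across families (re-drawn on the rare collision).
    """
    rng = np.random.default_rng(spec.seed)
    label_names = [f"fam{f:02d}" for f in range(spec.n_families)]
    consensus: list[str] = []
    motifs: list[list[tuple[int, str]]] = []
    members: list[list[str]] = []
    seen_motifs: set[str] = set()
    shared = (
        _random_protein(rng, spec.protein_length)
        if spec.shared_background
        else None
    )
    for _ in range(spec.n_families):
        base = shared if shared is not None else _random_protein(
            rng, spec.protein_length
        )
        starts = _place_motifs(
            rng,
            spec.protein_length,
            spec.motifs_per_family,
            spec.motif_length,
            spec.motif_margin,
        )
        fam_motifs: list[tuple[int, str]] = []
        chars = list(base)
        for s in starts:
            motif = _random_protein(rng, spec.motif_length)
            while motif in seen_motifs:
                motif = _random_protein(rng, spec.motif_length)
            seen_motifs.add(motif)
            chars[s : s + spec.motif_length] = motif
            fam_motifs.append((s, motif))
        cons = "".join(chars)
        in_motif = np.zeros(spec.protein_length, dtype=bool)
        for s, m in fam_motifs:
            in_motif[s : s + len(m)] = True

        fam_members: list[str] = []
        rate = spec.within_family_substitution_rate
        for _ in range(spec.members_per_family):
            mchars = list(cons)
            hits = np.flatnonzero(
                (rng.random(spec.protein_length) < rate) & ~in_motif
            )
            for p in hits:
                current = mchars[p]
                alt = AMINO_ACIDS[rng.integers(0, 19)]
                # uniform over the 19 residues different from the current one
                mchars[p] = alt if alt != current else AMINO_ACIDS[19]
            fam_members.append("".join(mchars))
        consensus.append(cons)
        motifs.append(fam_motifs)
        members.append(fam_members)
    return ProteinFamilies(label_names, consensus, motifs, members, spec)


def reverse_translate(protein: str, seed: int | np.random.Generator) -> str:
    """Reverse-translate a peptide to a CDS, codons uniform per position.

    Translating the output in frame 0 recovers the input exactly.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    codons = []
    for aa in protein:
        try:
            options = AA_TO_CODONS[aa]
        except KeyError:
            raise ValueError(f"unknown residue symbol: {aa!r}") from None
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


def inject_errors(
    sequence: str,
    config: ReadSimConfig,
    rng: np.random.Generator,
    return_counts: bool = False,
) -> str | tuple[str, dict[str, int]]:
    """Apply i.i.d. per-base substitution/insertion/deletion errors.

    Each base is hit with probability ``config.error_rate``; the error type
    is drawn from ``config.error_ratio``. A substitution replaces the base
    with a uniformly chosen different base; an insertion adds one uniform
    base after the position; a deletion removes the base.
    """
    counts = {"sub": 0, "ins": 0, "del": 0, "bases": len(sequence)}
    if config.error_rate == 0.0 or not sequence:
        return (sequence, counts) if return_counts else sequence
    src = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    n = len(src)
    hit = rng.random(n) < config.error_rate
    n_hit = int(hit.sum())
    if n_hit == 0:
        return (sequence, counts) if return_counts else sequence
    kinds = rng.choice(3, size=n_hit, p=np.asarray(config.error_ratio))
    # substitutions: shift by 1-3 positions in the base ring A->C->G->T->A
    sub_shift = rng.integers(1, 4, size=n_hit)
    ins_base = _BASES[rng.integers(0, 4, size=n_hit)]

    out = np.empty(2 * n, dtype=np.uint8)  # worst case: every base inserts
    base_idx = {65: 0, 67: 1, 71: 2, 84: 3}
    pos = 0
    k = 0
    for i in range(n):
        if not hit[i]:
            out[pos] = src[i]
            pos += 1
            continue
        kind = kinds[k]
        if kind == 0:  # substitution
            out[pos] = _BASES[(base_idx[src[i]] + sub_shift[k]) % 4]
            pos += 1
            counts["sub"] += 1
        elif kind == 1:  # insertion after the base
            out[pos] = src[i]
            out[pos + 1] = ins_base[k]
            pos += 2
            counts["ins"] += 1
        else:  # deletion
            counts["del"] += 1
        k += 1
    result = out[:pos].tobytes().decode("ascii")
    return (result, counts) if return_counts else result


def _draw_read_length(
    rng: np.random.Generator,
    model: tuple[float, float] | None,
    ref_len: int,
) -> int:
    if model is None:
        return ref_len
    mean, sd = model
    if mean > ref_len:
        warnings.warn(
            "read_length_model mean exceeds reference length; clamping"
        )
        return ref_len
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    length = int(round(rng.lognormal(mu, math.sqrt(sigma2))))
    return max(30, min(length, ref_len))


def simulate_reads(
    references: ReferenceSet, config: ReadSimConfig
) -> LabeledDataset:
    """Sample error-containing reads from labeled references to coverage.

    Per reference, reads are drawn (uniform start positions) until the sum
    of read lengths reaches ``coverage x reference length``. Labels are
    inherited. With ``strand="both"`` every other read is reverse-
    complemented. Deterministic given ``config.seed``: each read uses an RNG
    keyed by (seed, reference index, read index), so reads are independent
    of iteration order.
    """
    if not references.sequences:
        raise ValueError("references must be non-empty")
    reads: list[DnaRead] = []
    for ref_i, (ref, label) in enumerate(
        zip(references.sequences, references.labels)
    ):
        target = config.coverage * len(ref)
        got = 0.0
        k = 0
        while got < target:
            rng = np.random.default_rng([config.seed, ref_i, k])
            rlen = _draw_read_length(rng, config.read_length_model, len(ref))
            start = int(rng.integers(0, len(ref) - rlen + 1))
            frag = ref[start : start + rlen]
            strand = "+"
            if config.strand == "both" and k % 2 == 1:
                frag = reverse_complement(frag)
                strand = "-"
            frag = inject_errors(frag, config, rng)
            name = references.label_names[label] if label != OUTLIER else "outlier"
            reads.append(
                DnaRead(
                    read_id=f"{name}.ref{ref_i}.{k}{strand}",
                    sequence=frag,
                    true_label=label,
                    source_frame_offset=start % 3,
                )
            )
            got += rlen
            k += 1
    return LabeledDataset(reads, references.label_names)


def make_references(
    families: ProteinFamilies,
    members: list[list[str]] | None = None,
    seed: int = 0,
) -> ReferenceSet:
    """Reverse-translate family members into a labeled CDS set."""
    seqs: list[str] = []
    labels: list[int] = []
    src = members if members is not None else families.members
    counter = 0
    for fam_i, fam_members in enumerate(src):
        for protein in fam_members:
            rng = np.random.default_rng([seed, counter])
            seqs.append(reverse_translate(protein, rng))
            labels.append(fam_i)
            counter += 1
    return ReferenceSet(seqs, labels, list(families.label_names))


def split_members(
    families: ProteinFamilies, train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[list[str]], list[list[str]]]:
    """Split each family's members into train/test BEFORE simulation.

    Splitting references first guarantees no coding sequence contributes
    reads to both sides. Every family keeps at least one member per side.
    """
    rng = np.random.default_rng(seed)
    train: list[list[str]] = []
    test: list[list[str]] = []
    for fam_members in families.members:
        n = len(fam_members)
        order = rng.permutation(n)
        n_train = min(max(1, int(round(train_fraction * n))), n - 1)
        train.append([fam_members[i] for i in order[:n_train]])
        test.append([fam_members[i] for i in order[n_train:]])
    return train, test


def generate_outliers(
    n: int,
    length_model: tuple[float, float] | None = None,
    seed: int = 0,
    mode: str = "decoy",
    avoid_motifs: list[str] | tuple[str, ...] = (),
    family_spec: FamilySpec | None = None,
    sim_config: ReadSimConfig | None = None,
) -> LabeledDataset:
    """Generate reads that carry no trained domain (label = OUTLIER).

    mode "uniform": uniform-random DNA of the configured length.
    mode "decoy" (default): reads simulated from decoy families built with
    an independent seed and verified motif-disjoint from ``avoid_motifs``
    (exact substring check against every decoy member protein).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return LabeledDataset([], [])
    if mode == "uniform":
        reads = []
        for i in range(n):
            rng = np.random.default_rng([seed, 7, i])
            length = _draw_read_length(rng, length_model, 10**9)
            if length_model is None:
                length = 360
            seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
            reads.append(DnaRead(f"outlier.{i}", seq, OUTLIER))
        return LabeledDataset(reads, [])
    if mode != "decoy":
        raise ValueError("mode must be 'uniform' or 'decoy'")

    spec = family_spec or FamilySpec()
    for attempt in range(20):
        decoy_spec = FamilySpec(
            n_families=spec.n_families,
            protein_length=spec.protein_length,
            motifs_per_family=spec.motifs_per_family,
            motif_length=spec.motif_length,
            within_family_substitution_rate=spec.within_family_substitution_rate,
            members_per_family=spec.members_per_family,
            seed=int(np.random.default_rng([seed, 11, attempt]).integers(2**31)),
        )
        decoys = generate_families(decoy_spec)
        clash = any(
            motif in protein
            for motif in avoid_motifs
            for fam in decoys.members
            for protein in fam
        )
        if not clash:
            break
    else:  # pragma: no cover - probability ~ (20 L / 20^m)^20
        raise RuntimeError("could not build motif-disjoint decoy families")

    refs = make_references(decoys, seed=seed + 13)
    cfg = sim_config or ReadSimConfig(
        error_rate=0.0, coverage=1.0, read_length_model=length_model,
        seed=seed + 17,
    )
    # draw reads round-robin over decoy references until n are collected
    reads = []
    k = 0
    while len(reads) < n:
        ref_i = k % len(refs.sequences)
        rng = np.random.default_rng([cfg.seed, ref_i, k])
        ref = refs.sequences[ref_i]
        rlen = _draw_read_length(rng, cfg.read_length_model, len(ref))
        start = int(rng.integers(0, len(ref) - rlen + 1))
        frag = inject_errors(ref[start : start + rlen], cfg, rng)
        reads.append(DnaRead(f"outlier.{k}", frag, OUTLIER, start % 3))
        k += 1
    return LabeledDataset(reads, [])
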