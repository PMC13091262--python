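"""Synthetic MSA and ground-truth region generation.

Builds the benchmark inputs from scratch: a random parent amino-acid
sequence, gap/substitution-mutated children aligned to it, and a set of
named, non-overlapping regions (the ground-truth SBE definitions with
their SBRE names).

Coordinates are 1-based inclusive alignment columns throughout. Because
children only substitute or gap positions in place (no insertions),
alignment columns coincide with parent residue indices.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

GAP = "-"
DEFAULT_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
DEFAULT_NAME_POOL = (
    "Mutation Hotspot",
    "Low Conservation",
    "Binding Site",
    "Structural Motif",
)


class GenerationError(RuntimeError):
    """Raised when region placement is geometrically infeasible."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic benchmark generator.

    Defaults reproduce the study conditions: a 180-residue parent, nine
    children with per-site substitution probability 0.1 and gap
    probability 0.05, and two to five named regions of length 10-30
    separated by at least four residues.
    """

    parent_length: int = 180
    n_sequences: int = 10
    p_mut: float = 0.1
    p_gap: float = 0.05
    alphabet: str = DEFAULT_ALPHABET
    region_count_range: tuple[int, int] = (2, 5)
    region_length_range: tuple[int, int] = (10, 30)
    min_inter_region_gap: int = 4
    name_pool: tuple[str, ...] = DEFAULT_NAME_POOL

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mut <= 1.0:
            raise ValueError(f"p_mut must be in [0, 1], got {self.p_mut}")
        if not 0.0 <= self.p_gap <= 1.0:
            raise ValueError(f"p_gap must be in [0, 1], got {self.p_gap}")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet letters must be distinct")
        if GAP in self.alphabet:
            raise ValueError("alphabet must not contain the gap symbol")
        lo, hi = self.region_count_range
        if not (1 <= lo <= hi):
            raise ValueError(f"empty region_count_range {self.region_count_range}")
        lo, hi = self.region_length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"empty region_length_range {self.region_length_range}")
        if self.min_inter_region_gap < 0:
            raise ValueError("min_inter_region_gap must be >= 0")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.parent_length < 0:
            raise ValueError("parent_length must be >= 0")

    def to_dict(self) -> dict:
        return {
            "parent_length": self.parent_length,
            "n_sequences": self.n_sequences,
            "p_mut": self.p_mut,
            "p_gap": self.p_gap,
            "alphabet": self.alphabet,
            "region_count_range": list(self.region_count_range),
            "region_length_range": list(self.region_length_range),
            "min_inter_region_gap": self.min_inter_region_gap,
            "name_pool": list(self.name_pool),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("region_count_range", "region_length_range", "name_pool"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class RegionAnnotation:
    """One ground-truth region: its name (SBRE) and its 1-based
    inclusive start/end alignment columns (the SBE definition)."""

    sbre: str
    start: int
    end: int
    color: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def with_color(self, color: str) -> "RegionAnnotation":
        return replace(self, color=color)


@dataclass(frozen=True)
class SyntheticMSA:
    """An alignment of equal-length rows; row 0 is the gap-free parent."""

    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.sequences}
        if len(widths) > 1:
            raise ValueError("all MSA rows must have equal length")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def ids(self) -> list[str]:
        return ["parent"] + [f"child_{i}" for i in range(1, self.n_sequences)]


@dataclass(frozen=True)
class Dataset:
    """One benchmark item: an MSA plus its ground-truth regions."""

    dataset_id: str
    msa: SyntheticMSA
    regions: tuple[RegionAnnotation, ...]
    seed: int

    def __post_init__(self) -> None:
        starts = [r.start for r in self.regions]
        if starts != sorted(starts):
            raise ValueError("regions must be sorted by start")

    @property
    def truth_names(self) -> list[str]:
        return [r.sbre for r in self.regions]


def generate_parent(
    length: int, alphabet: str = DEFAULT_ALPHABET, rng: Optional[np.random.Generator] = None
) -> str:
    """Draw a random residue sequence, i.i.d. uniform over the alphabet."""
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    rng = np.random.default_rng() if rng is None else rng
    letters = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
    return rng.choice(letters, size=length).tobytes().decode("ascii")


def derive_child(
    parent: str,
    p_mut: float,
    p_gap: float,
    rng: np.random.Generator,
    alphabet: str = DEFAULT_ALPHABET,
) -> str:
    """Mutate a parent into an aligned child, position by position.

    Each site independently becomes a gap with probability ``p_gap``;
    otherwise it is substituted (uniformly over the other 19 residues)
    with probability ``p_mut``; otherwise the parent residue is copied.
    Gapping is evaluated first so the marginal gap rate is exactly
    ``p_gap``, and substitutions always change the residue so the
    observed mismatch rate among non-gap sites is exactly ``p_mut``.
    The output has the parent's length: columns are never inserted.
    """
    if not parent:
        raise ValueError("parent must be non-empty")
    if not 0.0 <= p_mut <= 1.0:
        raise ValueError(f"p_mut must be in [0, 1], got {p_mut}")
    if not 0.0 <= p_gap <= 1.0:
        raise ValueError(f"p_gap must be in [0, 1], got {p_gap}")

    n = len(parent)
    child = np.frombuffer(parent.encode("ascii"), dtype=np.uint8).copy()
    gap_mask = rng.random(n) < p_gap
    mut_mask = (rng.random(n) < p_mut) & ~gap_mask

    if mut_mask.any():
        letters = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
        k = len(letters)
        # index of each parent residue in the alphabet
        lut = np.full(256, -1, dtype=np.int64)
        lut[letters] = np.arange(k)
        parent_idx = lut[child[mut_mask]]
        if (parent_idx < 0).any():
            raise ValueError("parent contains letters outside the alphabet")
        # uniform over the k-1 other residues: skip the parent's slot
        draw = rng.integers(0, k - 1, size=int(mut_mask.sum()))
        draw = np.where(draw >= parent_idx, draw + 1, draw)
        child[mut_mask] = letters[draw]

    child[gap_mask] = ord(GAP)
    return child.tobytes().decode("ascii")


def build_msa(config: GeneratorConfig, rng: np.random.Generator) -> SyntheticMSA:
    """Assemble the alignment: gap-free parent plus mutated children."""
    parent = generate_parent(config.parent_length, config.alphabet, rng)
    rows = [parent]
    for _ in range(config.n_sequences - 1):
        rows.append(
            derive_child(parent, config.p_mut, config.p_gap, rng, config.alphabet)
        )
    return SyntheticMSA(sequences=tuple(rows))


def sample_regions(
    n_columns: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    max_attempts: int = 1000,
    max_rounds: int = 10,
) -> list[RegionAnnotation]:
    """Place unnamed regions by rejection sampling.

    Samples a region count uniformly over the configured range, then
    lengths uniformly, then start columns uniformly; a draw is accepted
    when, after sorting, consecutive regions are separated by at least
    ``min_inter_region_gap`` columns. On ``max_attempts`` rejections the
    lengths are resampled; after ``max_rounds`` such rounds the geometry
    is declared infeasible.
    """
    c_lo, c_hi = config.region_count_range
    l_lo, l_hi = config.region_length_range
    gap = config.min_inter_region_gap
    count = int(rng.integers(c_lo, c_hi + 1))

    for _ in range(max_rounds):
        lengths = rng.integers(l_lo, l_hi + 1, size=count)
        if int(lengths.sum()) + gap * (count - 1) <= n_columns:
            for _ in range(max_attempts):
                starts = np.array(
                    [rng.integers(1, n_columns - L + 2) for L in lengths]
                )
                order = np.argsort(starts, kind="stable")
                s, L = starts[order], lengths[order]
                e = s + L - 1
                if np.all(s[1:] - e[:-1] - 1 >= gap):
                    return [
                        RegionAnnotation(sbre="", start=int(a), end=int(b))
                        for a, b in zip(s, e)
                    ]
    raise GenerationError(
        f"cannot place {count} regions of lengths in [{l_lo}, {l_hi}] with "
        f"inter-region gap >= {gap} into {n_columns} columns "
        f"after {max_rounds} rounds of {max_attempts} attempts"
    )


def assign_region_names(
    regions: Sequence[RegionAnnotation],
    name_pool: Sequence[str],
    rng: np.random.Generator,
) -> list[RegionAnnotation]:
    """Name regions: a uniform base-name draw plus an A, B, C... suffix.

    Suffix letters run per base name in ascending start order; a base
    name drawn only once still gets suffix "A", so full names are always
    distinct within a dataset.
    """
    starts = [r.start for r in regions]
    if starts != sorted(starts):
        raise ValueError("regions must be sorted by start")
    bases = [name_pool[int(i)] for i in rng.integers(0, len(name_pool), size=len(regions))]
    counters: dict[str, int] = {}
    named = []
    for region, base in zip(regions, bases):
        k = counters.get(base, 0)
        if k >= 26:
            raise GenerationError(f"more than 26 regions share base name {base!r}")
        counters[base] = k + 1
        named.append(replace(region, sbre=f"{base} {string.ascii_uppercase[k]}"))
    return named


def validate_dataset(ds: Dataset, config: GeneratorConfig) -> None:
    """Check every structural constraint of a generated dataset.

    Raises ``ValueError`` naming the first violated constraint: row
    count and width, gap-free parent, region count/length ranges,
    inter-region separation, column bounds, and name uniqueness.
    """
    msa = ds.msa
    if msa.n_sequences != config.n_sequences:
        raise ValueError(f"{ds.dataset_id}: expected {config.n_sequences} rows")
    if msa.n_columns != config.parent_length:
        raise ValueError(f"{ds.dataset_id}: expected {config.parent_length} columns")
    if GAP in msa.sequences[0]:
        raise ValueError(f"{ds.dataset_id}: parent row contains gaps")
    c_lo, c_hi = config.region_count_range
    if not c_lo <= len(ds.regions) <= c_hi:
        raise ValueError(f"{ds.dataset_id}: region count {len(ds.regions)} outside range")
    names = [r.sbre for r in ds.regions]
    if len(names) != len(set(names)):
        raise ValueError(f"{ds.dataset_id}: duplicate region names")
    l_lo, l_hi = config.region_length_range
    prev_end = None
    for r in ds.regions:
        if not 1 <= r.start <= r.end <= msa.n_columns:
            raise ValueError(f"{ds.dataset_id}: region {r.sbre!r} outside columns")
        if not l_lo <= r.length <= l_hi:
            raise ValueError(f"{ds.dataset_id}: region {r.sbre!r} length {r.length}")
        if prev_end is not None and r.start - prev_end - 1 < config.min_inter_region_gap:
            raise ValueError(f"{ds.dataset_id}: separation before {r.sbre!r} too small")
        prev_end = r.end


def generate_dataset(
    dataset_id: str, config: GeneratorConfig, seed: int
) -> Dataset:
    """Generate one complete dataset from a single seed."""
    rng = np.random.default_rng(seed)
    msa = build_msa(config, rng)
    regions = sample_regions(msa.n_columns, config, rng)
    regions = assign_region_names(regions, config.name_pool, rng)
    return Dataset(dataset_id=dataset_id, msa=msa, regions=tuple(regions), seed=seed)


def derive_seed(master_seed: int, index: int) -> int:
    """Per-dataset seed from a master seed and a counter (stable, < 2^31)."""
    return int(
        np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31)
    )


def generate_corpus(
    n_datasets: int, config: GeneratorConfig, master_seed: int
) -> list[Dataset]:
    """Generate a deterministic corpus of datasets.

    Each dataset uses its own RNG stream seeded from (master_seed, index),
    so corpora are reproducible and datasets are independent of corpus
    size and order of generation.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    datasets = []
    for i in range(n_datasets):
        dataset_id = f"msa_{i:03d}"
        try:
            datasets.append(generate_dataset(dataset_id, config, derive_seed(master_seed, i)))
        except GenerationError as exc:
            raise GenerationError(f"dataset {i} ({dataset_id}): {exc}") from exc
    return datasets
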