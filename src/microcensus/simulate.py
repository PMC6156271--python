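"""Synthetic 16S communities with known novelty structure.

Real novelty censuses rest on two databases that cannot ship with a package:
a cultured-isolate 16S reference set and environmental query sequences. This
module generates both with fully controlled ground truth, so that every
downstream stage — top-hit search, QC, binning, aggregation, extrapolation —
can be tested end to end.

The generative model is deliberately simple and analytically transparent:

* Reference sequences are i.i.d. uniform over ACGT (random unrelated 16S
  stand-ins; pairwise identity ~25%).
* An environmental query is a cultured reference with an exact number of
  substitutions, so its true identity to its parent is known to within
  1/(2L) of the requested value. No indels by default.
* Substitutions avoid the 10 terminal bases at each end so local-alignment
  end trimming cannot shift the optimal alignment and bias identity upward.
* Chimeras splice a prefix of one reference onto a suffix of another.
* Short-fragment artifacts embed 150–290 bp of (mutated) parental sequence
  in random flanks, emulating spurious hits to small conserved regions.
* Per-query scaffold read depths are log-normal, clipped below at 1, giving
  strictly positive heavy-tailed coverages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import CutoffLadder, NoveltyBin, assign_bin
from .errors import DataError, ParameterError
from .util import largest_remainder, round_half_away

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Default per-bin (low, high) percent-identity ranges for query generation.
#: Kept >= 0.4 points inside the 96.6 / 86.0 cutoffs so that rounding the
#: substitution count can never flip a truth bin, and bounded below at 75 so
#: substitution-only queries always retain full-length local alignments.
DEFAULT_IDENTITY_RANGES: dict[NoveltyBin, tuple[float, float]] = {
    NoveltyBin.CULTURED_SPECIES_TO_GENUS: (97.0, 100.0),
    NoveltyBin.UNCULTURED_GENUS_TO_CLASS: (86.5, 96.5),
    NoveltyBin.UNCULTURED_PHYLUM_PLUS: (75.0, 85.5),
}

_PHYLA = {
    "bacteria": ["Proteobacteria", "Firmicutes", "Bacteroidetes", "Chloroflexi",
                 "Actinobacteria", "Planctomycetes"],
    "archaea": ["Euryarchaeota", "Crenarchaeota", "Thaumarchaeota"],
}


@dataclass(frozen=True)
class RefRecord:
    """One reference 16S sequence with its provenance."""

    id: str
    sequence: str
    domain: str
    taxonomy: str
    cultured: bool = True


@dataclass(frozen=True)
class ReferenceSet:
    """A 16S reference database (cultured isolates or environmental clones)."""

    records: tuple[RefRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DataError("reference ids must be unique")
        for r in self.records:
            if not r.sequence or set(r.sequence) - set("ACGT"):
                raise DataError(f"reference {r.id}: empty or non-ACGT sequence")
            if len(r.taxonomy.split(";")) != 7:
                raise DataError(f"reference {r.id}: taxonomy must have 7 ranks")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sequences(self) -> dict[str, str]:
        return {r.id: r.sequence for r in self.records}

    def by_id(self, ref_id: str) -> RefRecord:
        for r in self.records:
            if r.id == ref_id:
                return r
        raise KeyError(ref_id)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _synthetic_taxonomy(domain: str, index: int, rng: np.random.Generator) -> str:
    phylum = _PHYLA[domain][int(rng.integers(len(_PHYLA[domain])))]
    dom = domain.capitalize()
    return (
        f"{dom};{phylum};Class{index:03d};Order{index:03d};"
        f"Family{index:03d};Genus{index:03d};Species{index:03d}"
    )


def generate_reference_db(
    n_bacteria: int,
    n_archaea: int,
    length: int = 1500,
    seed: int = 0,
) -> ReferenceSet:
    """Generate a cultured 16S reference database of random sequences.

    Each record gets a synthetic 7-rank taxonomy with its own genus and
    species. Deterministic for a fixed seed.
    """
    if n_bacteria < 0 or n_archaea < 0 or n_bacteria + n_archaea < 1:
        raise ParameterError("need at least one reference record")
    if length < 100:
        raise ParameterError("reference length must be >= 100 bp")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_bacteria):
        records.append(RefRecord(
            id=f"bact_{i + 1:04d}",
            sequence=_random_sequence(rng, length),
            domain="bacteria",
            taxonomy=_synthetic_taxonomy("bacteria", i + 1, rng),
        ))
    for i in range(n_archaea):
        records.append(RefRecord(
            id=f"arch_{i + 1:04d}",
            sequence=_random_sequence(rng, length),
            domain="archaea",
            taxonomy=_synthetic_taxonomy("archaea", i + 1, rng),
        ))
    return ReferenceSet(tuple(records))


def mutate_to_identity(sequence: str, target_identity: float, seed) -> str:
    """Substitute bases to bring Hamming identity to ``target_identity``.

    Exactly ``round((1 - target/100) * L)`` distinct positions are changed,
    all within ``[10, L-11]`` (0-based) so the 10 bp at each end stay clean.
    Substitutions only — the output has the same length as the input and its
    ungapped identity to the input equals the target within 1/(2L).

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if not (0.0 < target_identity <= 100.0):
        raise ParameterError("target_identity must be in (0, 100]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = len(sequence)
    n_sub = round_half_away((1.0 - target_identity / 100.0) * length)
    eligible = length - 20
    if n_sub > eligible:
        raise ParameterError(
            f"{n_sub} substitutions requested but only {eligible} internal "
            f"positions are eligible"
        )
    if n_sub == 0:
        return sequence
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    positions = rng.choice(np.arange(10, length - 10), size=n_sub, replace=False)
    for pos in positions:
        current = arr[pos]
        choices = _BASES[_BASES != current]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def achieved_identity(length: int, target_identity: float) -> float:
    """Exact Hamming identity produced by :func:`mutate_to_identity`."""
    n_sub = round_half_away((1.0 - target_identity / 100.0) * length)
    return 100.0 * (length - n_sub) / length


def apply_indels(sequence: str, n_indels: int, seed) -> str:
    """Apply single-base insertions/deletions at random internal positions.

    Each event is an insertion or deletion with equal probability, placed
    at least 10 bp from either end. Indels make the true identity only
    approximately known (gap columns enter the alignment denominator), so
    they are off by default in :class:`CommunitySpec` and excluded from the
    standard study conditions.
    """
    if n_indels < 0:
        raise ParameterError("n_indels must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = list(sequence)
    for _ in range(n_indels):
        if len(seq) < 25:
            raise ParameterError("sequence too short for further indels")
        pos = int(rng.integers(10, len(seq) - 10))
        if rng.random() < 0.5:
            seq.insert(pos, str(rng.choice(_BASES).decode()))
        else:
            del seq[pos]
    return "".join(seq)


def make_chimera(seq_a: str, seq_b: str, breakpoint: float) -> str:
    """Splice a prefix of ``seq_a`` onto a suffix of ``seq_b``.

    The output is ``seq_a[:round(bp*len(a))] + seq_b[round(bp*len(b)):]``,
    emulating an assembly or PCR chimera; its length is within 1 bp of the
    breakpoint-weighted mean of the parental lengths.
    """
    if not (0.2 <= breakpoint <= 0.8):
        raise ParameterError("breakpoint must be within [0.2, 0.8]")
    if len(seq_a) < 500 or len(seq_b) < 500:
        raise ParameterError("chimera parents must be >= 500 bp")
    cut_a = round_half_away(breakpoint * len(seq_a))
    cut_b = round_half_away(breakpoint * len(seq_b))
    return seq_a[:cut_a] + seq_b[cut_b:]


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of one simulated environmental community.

    ``bin_proportions`` orders the three novelty bins from least to most
    novel and must sum to 1. ``identity_ranges`` gives each bin's (low,
    high) percent-identity interval and must be consistent with the active
    cutoffs. ``depth_law`` is the (mean, sd) of log read depth. With
    ``allocation="largest_remainder"`` (default) per-sample bin counts are
    deterministic; ``"multinomial"`` draws them instead.
    """

    environment: str
    n_samples: int = 1
    n_seqs_per_sample: int = 100
    bin_proportions: tuple[float, float, float] = (0.2, 0.3, 0.5)
    identity_ranges: dict[NoveltyBin, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_IDENTITY_RANGES)
    )
    chimera_rate: float = 0.0
    short_fragment_rate: float = 0.0
    indel_rate: float = 0.0  # expected indels per kb of clean query
    depth_law: tuple[float, float] = (1.0, 1.0)
    dataset_type: str = "metagenome"
    seed: int = 0
    allocation: str = "largest_remainder"

    def validate(self, cutoffs: CutoffLadder) -> None:
        if self.n_samples < 1 or self.n_seqs_per_sample < 1:
            raise ParameterError("n_samples and n_seqs_per_sample must be >= 1")
        if abs(sum(self.bin_proportions) - 1.0) > 1e-9:
            raise ParameterError("bin_proportions must sum to 1")
        if not (0.0 <= self.chimera_rate <= 1.0 and 0.0 <= self.short_fragment_rate <= 1.0):
            raise ParameterError("rates must be in [0, 1]")
        if self.indel_rate < 0:
            raise ParameterError("indel_rate must be >= 0")
        if self.allocation not in ("largest_remainder", "multinomial"):
            raise ParameterError(f"unknown allocation mode {self.allocation!r}")
        lo1, _ = self.identity_ranges[NoveltyBin.CULTURED_SPECIES_TO_GENUS]
        _, hi3 = self.identity_ranges[NoveltyBin.UNCULTURED_PHYLUM_PLUS]
        if lo1 <= cutoffs.genus_cutoff:
            raise ParameterError("bin-1 identity range must lie above the genus cutoff")
        if hi3 >= cutoffs.phylum_cutoff:
            raise ParameterError("bin-3 identity range must lie below the phylum cutoff")


@dataclass
class EnvironmentDataset:
    """Simulated queries with their metadata and truth labels.

    ``metadata`` columns: query_id, domain, dataset_type, sample_id,
    environment, read_depth, taxonomy. ``truth`` columns: query_id,
    parent_ref_id (two ``;``-joined ids for chimeras), true_identity (NaN
    for chimeras), true_bin ("" for chimeras), is_chimera,
    is_short_fragment.
    """

    sequences: dict[str, str]
    metadata: pd.DataFrame
    truth: pd.DataFrame


def _truncate_taxonomy(taxonomy: str, bin_: NoveltyBin) -> str:
    """Coarsen a parent taxonomy according to the query's novelty.

    Novel-genus-to-class queries keep domain/phylum/class; novel-phylum
    queries keep domain/phylum only; remaining ranks become "unclassified",
    emulating how classifiers leave divergent sequences unresolved.
    """
    ranks = taxonomy.split(";")
    keep = {NoveltyBin.CULTURED_SPECIES_TO_GENUS: 7,
            NoveltyBin.UNCULTURED_GENUS_TO_CLASS: 3,
            NoveltyBin.UNCULTURED_PHYLUM_PLUS: 2}[bin_]
    return ";".join(ranks[:keep] + ["unclassified"] * (7 - keep))


def generate_environment_dataset(
    spec: CommunitySpec,
    refs: ReferenceSet,
    cutoffs: CutoffLadder | None = None,
) -> EnvironmentDataset:
    """Simulate one environment's query dataset with truth labels.

    Per sample, chimera and fragment counts are ``round(rate * n)``; the
    remaining queries are allocated to novelty bins (largest-remainder by
    default) and each is derived from a uniformly chosen cultured reference
    by exact substitution. Deterministic for a fixed ``spec.seed``.
    """
    cutoffs = cutoffs or CutoffLadder()
    spec.validate(cutoffs)
    if len(refs) == 0:
        raise DataError("reference set is empty")
    rng = np.random.default_rng(spec.seed)
    records = list(refs)
    seqs: dict[str, str] = {}
    meta_rows = []
    truth_rows = []
    mu, sigma = spec.depth_law

    for s in range(1, spec.n_samples + 1):
        sample_id = f"{spec.environment}_s{s:02d}"
        n = spec.n_seqs_per_sample
        n_chim = round_half_away(spec.chimera_rate * n)
        n_frag = round_half_away(spec.short_fragment_rate * n)
        n_clean = n - n_chim - n_frag
        if spec.allocation == "largest_remainder":
            counts = largest_remainder(n_clean, spec.bin_proportions)
        else:
            counts = list(rng.multinomial(n_clean, spec.bin_proportions))
        plan: list[tuple[str, NoveltyBin | None]] = []
        for bin_, c in zip(NoveltyBin, counts):
            plan.extend(("clean", bin_) for _ in range(c))
        plan.extend(("chimera", None) for _ in range(n_chim))
        plan.extend(("fragment", None) for _ in range(n_frag))

        for i, (kind, bin_) in enumerate(plan, start=1):
            qid = f"{sample_id}_q{i:04d}"
            depth = float(max(1.0, rng.lognormal(mu, sigma)))
            if kind == "clean":
                parent = records[int(rng.integers(len(records)))]
                lo, hi = spec.identity_ranges[bin_]
                target = float(rng.uniform(lo, hi))
                seq = mutate_to_identity(parent.sequence, target, rng)
                if spec.indel_rate > 0:
                    n_indels = round_half_away(
                        spec.indel_rate * len(seq) / 1000.0)
                    seq = apply_indels(seq, n_indels, rng)
                ident = achieved_identity(len(parent.sequence), target)
                true_bin = assign_bin(ident, cutoffs)
                if true_bin is not bin_:  # ranges guarantee this never fires
                    raise ParameterError(
                        f"identity range for {bin_.label} crosses a cutoff"
                    )
                seqs[qid] = seq
                meta_rows.append((qid, parent.domain, spec.dataset_type, sample_id,
                                  spec.environment, depth,
                                  _truncate_taxonomy(parent.taxonomy, true_bin)))
                truth_rows.append((qid, parent.id, ident, true_bin.label,
                                   False, False))
            elif kind == "fragment":
                parent = records[int(rng.integers(len(records)))]
                target = float(rng.uniform(90.0, 99.0))
                mutated = mutate_to_identity(parent.sequence, target, rng)
                frag_len = int(rng.integers(150, 291))
                length = len(parent.sequence)
                start = int(rng.integers(10, length - frag_len - 10))
                left = _random_sequence(rng, start)
                right = _random_sequence(rng, length - start - frag_len)
                seqs[qid] = left + mutated[start:start + frag_len] + right
                ident = achieved_identity(length, target)
                true_bin = assign_bin(ident, cutoffs)
                meta_rows.append((qid, parent.domain, spec.dataset_type, sample_id,
                                  spec.environment, depth,
                                  _truncate_taxonomy(parent.taxonomy, true_bin)))
                truth_rows.append((qid, parent.id, ident, true_bin.label,
                                   False, True))
            else:  # chimera
                ia, ib = rng.choice(len(records), size=2, replace=False)
                pa, pb = records[int(ia)], records[int(ib)]
                bp = float(rng.uniform(0.25, 0.75))
                seqs[qid] = make_chimera(pa.sequence, pb.sequence, bp)
                meta_rows.append((qid, pa.domain, spec.dataset_type, sample_id,
                                  spec.environment, depth, pa.taxonomy))
                truth_rows.append((qid, f"{pa.id};{pb.id}", np.nan, "",
                                   True, False))

    metadata = pd.DataFrame(
        meta_rows,
        columns=["query_id", "domain", "dataset_type", "sample_id",
                 "environment", "read_depth", "taxonomy"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["query_id", "parent_ref_id", "true_identity", "true_bin",
                 "is_chimera", "is_short_fragment"],
    )
    return EnvironmentDataset(sequences=seqs, metadata=metadata, truth=truth)


def generate_environmental_db(
    refs: ReferenceSet,
    n: int,
    identity_range: tuple[float, float] = (88.0, 97.0),
    seed: int = 0,
) -> ReferenceSet:
    """Derive an uncultured "environmental clone" database from cultured refs.

    Stands in for the environmental-DNA database used as the second screen
    in chimera detection: each record is a cultured reference mutated to a
    uniform identity within ``identity_range`` and marked uncultured.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if len(refs) == 0:
        raise DataError("reference set is empty")
    rng = np.random.default_rng(seed)
    records = list(refs)
    out = []
    for i in range(n):
        parent = records[int(rng.integers(len(records)))]
        target = float(rng.uniform(*identity_range))
        out.append(RefRecord(
            id=f"env_{i + 1:04d}",
            sequence=mutate_to_identity(parent.sequence, target, rng),
            domain=parent.domain,
            taxonomy=_truncate_taxonomy(parent.taxonomy,
                                        NoveltyBin.UNCULTURED_GENUS_TO_CLASS),
            cultured=False,
        ))
    return ReferenceSet(tuple(out))


def with_seed(spec: CommunitySpec, seed: int) -> CommunitySpec:
    """Copy of ``spec`` with a different seed (convenience for sweeps)."""
    return replace(spec, seed=seed)
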