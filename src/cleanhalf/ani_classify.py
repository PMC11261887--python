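"""MinHash prefilter, taxonomic-context expansion, fragment ANI/AF and the
three-way species category decision.

Sketching uses canonical k-mers hashed with a fixed seeded 64-bit mix
(splitmix64), so sketches are reproducible across runs and platforms.  The
fragment ANI is a desk-scale analogue of fragment-mapping ANI tools: the
query is cut into consecutive fixed-length fragments, each fragment is
anchored to the reference window sharing the most anchor k-mers, and scored
by alignment identity.  Results are deliberately not bit-compatible with the
external Mash/FastANI binaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import log
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .io_formats import RANK_CODES, RANK_INDEX, TaxonomyString

DEFAULT_HASH_SEED = 42


@dataclass(frozen=True)
class MinHashParams:
    k: int = 16
    s: int = 5000
    d_max: float = 0.2
    v_max: float = 1.0  # pass-through; 1.0 disables the p-value filter
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        if self.k < 1 or self.k > 32:
            raise ValueError("k must be in [1, 32]")
        if self.s < 1:
            raise ValueError("sketch size must be >= 1")
        if not 0.0 <= self.d_max <= 1.0:
            raise ValueError("d_max must be in [0, 1]")


@dataclass(frozen=True)
class SpeciesCriteria:
    ani_min: float = 95.0
    af_min: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.ani_min <= 100.0:
            raise ValueError("ani_min must be in (0, 100]")
        if not 0.0 < self.af_min <= 1.0:
            raise ValueError("af_min must be in (0, 1]")


@dataclass(frozen=True)
class MinHashSketch:
    hashes: np.ndarray  # sorted ascending uint64, length <= params.s
    params: MinHashParams

    def __len__(self) -> int:
        return len(self.hashes)


@dataclass(frozen=True)
class AniResult:
    query: str
    best_ref: str | None
    ani: float
    af: float
    category: str  # same_species | changed_species | new_species
    expected_rep: str | None = None


# ---------------------------------------------------------------------------
# k-mer encoding and hashing

_NT_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _NT_CODE[_b] = _i


def _splitmix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Vectorised splitmix64 finaliser; uint64 arithmetic wraps by design."""
    z = x + np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all valid (ACGT-only) k-mers of ``seq`` in order."""
    vals = _NT_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    n = len(vals)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.uint64)
    invalid = (vals == 255).astype(np.int32)
    for j in range(k):
        codes = (codes << np.uint64(2)) | vals[j : j + m].astype(np.uint64)
    bad = np.convolve(invalid, np.ones(k, dtype=np.int32), mode="valid") > 0
    return codes[~bad]


def canonical_kmer_hashes(seq: str, k: int, hash_seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Hashes of canonical k-mers (min of forward and reverse complement)."""
    fwd = _kmer_codes(seq, k)
    rc_all = _kmer_codes(_revcomp_acgt(seq), k)[::-1]
    # fwd and rc arrays align positionally only when the sequence is pure
    # ACGT; with ambiguity codes both sides drop the same windows, keeping
    # alignment intact.
    if len(fwd) != len(rc_all):  # pragma: no cover - defensive
        raise AssertionError("forward/reverse k-mer streams misaligned")
    canon = np.minimum(fwd, rc_all)
    return _splitmix64(canon, hash_seed)


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def _revcomp_acgt(seq: str) -> str:
    return seq.upper().translate(_RC_TABLE)[::-1]


def sketch(seq: "str | Sequence[str]", params: MinHashParams | None = None) -> MinHashSketch:
    """Bottom-s sketch: the s smallest distinct canonical k-mer hashes.

    Accepts a single sequence or a collection of pieces (contigs); k-mers
    never span piece boundaries.
    """
    params = params or MinHashParams()
    pieces = (seq,) if isinstance(seq, str) else tuple(seq)
    if max((len(p) for p in pieces), default=0) < params.k:
        raise ValueError(f"no sequence piece reaches k={params.k}")
    all_hashes = [
        canonical_kmer_hashes(p, params.k, params.hash_seed)
        for p in pieces
        if len(p) >= params.k
    ]
    hashes = np.unique(np.concatenate(all_hashes))
    return MinHashSketch(hashes[: params.s], params)


def sketch_jaccard(a: MinHashSketch, b: MinHashSketch) -> float:
    """Mash-style Jaccard estimate from the bottom-s of the hash union."""
    if a.params != b.params:
        raise ValueError("sketches built with different parameters")
    union = np.union1d(a.hashes, b.hashes)
    s = min(a.params.s, len(union))
    if s == 0:
        return 0.0
    bottom = union[:s]
    shared = np.isin(bottom, a.hashes, assume_unique=True) & np.isin(
        bottom, b.hashes, assume_unique=True
    )
    return float(shared.sum() / s)


def mash_distance(a: MinHashSketch, b: MinHashSketch) -> float:
    """d = -ln(2j / (1+j)) / k, with j = 0 mapping to d = 1 by convention."""
    if a.params != b.params:
        raise ValueError("sketches built with different parameters")
    j = sketch_jaccard(a, b)
    if j <= 0.0:
        return 1.0
    d = -log(2.0 * j / (1.0 + j)) / a.params.k
    return min(max(d, 0.0), 1.0)


def ani_estimate(distance: float) -> float:
    return 100.0 * (1.0 - distance)


def prefilter_references(
    query: MinHashSketch,
    ref_sketches: Mapping[str, MinHashSketch],
    params: MinHashParams | None = None,
) -> list[str]:
    """Accessions with estimated ANI strictly above 80 % and distance within
    d_max (both screens applied; their intersection is taken)."""
    params = params or query.params
    out = []
    for acc, ref in ref_sketches.items():
        d = mash_distance(query, ref)
        if ani_estimate(d) > 80.0 and d <= params.d_max:
            out.append(acc)
    return out


def taxonomic_context(
    expected_tax: TaxonomyString,
    rep_metadata: Mapping[str, TaxonomyString],
    min_genomes: int = 100,
) -> list[str]:
    """Representatives from the expected genus, widened rank by rank
    (family, order, class, phylum) until at least ``min_genomes`` accumulate
    or the phylum is exhausted."""
    genus = expected_tax.named_at("g")
    start = "g"
    if genus is None or not any(
        meta.named_at("g") == genus for meta in rep_metadata.values()
    ):
        warnings.warn(
            "expected genus absent from representative metadata; "
            "starting context at family",
            stacklevel=2,
        )
        start = "f"
    selected: dict[str, None] = {}
    for code in reversed(RANK_CODES[RANK_INDEX["p"] : RANK_INDEX[start] + 1]):
        name = expected_tax.named_at(code)
        if name is None:
            continue
        for acc, meta in rep_metadata.items():
            if meta.named_at(code) == name:
                selected.setdefault(acc, None)
        if len(selected) >= min_genomes:
            break
    return list(selected)


# ---------------------------------------------------------------------------
# Fragment ANI

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-3,
    extend_gap_score=-1,
)


def _alignment_identity(a: str, b: str) -> float:
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / total if total else 0.0


Seqs = "str | Sequence[str]"


def _pieces(seqs: str | Sequence[str]) -> tuple[str, ...]:
    return (seqs,) if isinstance(seqs, str) else tuple(seqs)


def cut_fragments(seqs: str | Sequence[str], fragment_len: int) -> list[str]:
    """Consecutive non-overlapping fragments, cut per piece so no fragment
    straddles a contig boundary; trailing remainders are dropped."""
    return [
        piece[i * fragment_len : (i + 1) * fragment_len]
        for piece in _pieces(seqs)
        for i in range(len(piece) // fragment_len)
    ]


@lru_cache(maxsize=256)
def _anchor_index(
    ref_pieces: tuple[str, ...], k_anchor: int, min_len: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[np.ndarray, ...]]:
    """Anchor k-mer index over reference pieces.

    Pieces shorter than ``min_len`` cannot host a full-length fragment
    mapping and are excluded.  Returns (sorted codes, piece id per code,
    position-in-piece per code, encoded piece arrays).  Cached: the same
    representatives are queried repeatedly during a run.
    """
    codes_parts, piece_parts, pos_parts, arrs = [], [], [], []
    for piece in ref_pieces:
        if len(piece) < min_len:
            continue
        i = len(arrs)
        codes = _kmer_codes(piece, k_anchor)
        codes_parts.append(codes)
        piece_parts.append(np.full(len(codes), i, dtype=np.int64))
        pos_parts.append(np.arange(len(codes), dtype=np.int64))
        arrs.append(np.frombuffer(piece.upper().encode(), dtype=np.uint8))
    codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.uint64)
    piece_ids = np.concatenate(piece_parts) if piece_parts else np.empty(0, np.int64)
    positions = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
    order = np.argsort(codes, kind="stable")
    return codes[order], piece_ids[order], positions[order], tuple(arrs)


def fragment_ani(
    query_seq: str | Sequence[str],
    ref_seq: str | Sequence[str],
    fragment_len: int = 3000,
    k_anchor: int = 15,
    min_anchors: int = 3,
) -> tuple[float, float]:
    """One-directional fragment-mapping ANI.

    Each query piece (contig) is cut into floor(len/fragment_len)
    consecutive fragments; fragments never straddle piece boundaries.  Each
    fragment votes for the (reference piece, diagonal) sharing the most
    k_anchor-mers and is scored by alignment identity against the window on
    the best diagonal, clamped inside that piece.  Fragments whose best
    diagonal gathers fewer than ``min_anchors`` shared anchors are unmapped
    (a lone chance k-mer hit against an unrelated reference is not a
    mapping).  Returns (ANI percent over mapped fragments, mapped fraction).
    """
    frags = cut_fragments(query_seq, fragment_len)
    if not frags:
        raise ValueError(f"no query piece reaches fragment_len={fragment_len}")
    ref_tuple = _pieces(ref_seq)
    if max((len(p) for p in ref_tuple), default=0) < fragment_len:
        raise ValueError(f"no reference piece reaches fragment_len={fragment_len}")
    ref_sorted, ref_piece, ref_pos, ref_arrs = _anchor_index(
        ref_tuple, k_anchor, fragment_len
    )
    # combined vote key: piece id * span + shifted diagonal
    max_len = max(len(p) for p in ref_tuple)
    span = max_len + fragment_len + 2
    identities: list[float] = []
    for frag in frags:
        frag_codes = _kmer_codes(frag, k_anchor)
        if len(frag_codes) == 0:
            continue
        left = np.searchsorted(ref_sorted, frag_codes, side="left")
        right = np.searchsorted(ref_sorted, frag_codes, side="right")
        hits = right - left
        matched = np.nonzero(hits)[0]
        if len(matched) == 0:
            continue  # unmapped fragment
        reps = hits[matched]
        frag_pos = np.repeat(matched, reps).astype(np.int64)
        take = np.concatenate(
            [np.arange(left[m], right[m]) for m in matched]
        )
        diags = ref_pos[take] - frag_pos
        keys = ref_piece[take] * span + (diags + fragment_len)
        uniq, counts = np.unique(keys, return_counts=True)
        if counts.max() < min_anchors:
            continue  # unmapped: no credible diagonal
        best_key = int(uniq[np.argmax(counts)])
        piece_arr = ref_arrs[best_key // span]
        best_diag = best_key % span - fragment_len
        frag_arr = np.frombuffer(frag.encode(), dtype=np.uint8)
        # Clamp so the window lies fully inside the piece.
        start = min(max(0, best_diag), len(piece_arr) - fragment_len)
        window = piece_arr[start : start + fragment_len]
        ham = float(np.mean(frag_arr == window))
        # Ungapped comparison is optimal when the window sits on a
        # consistent diagonal; fall back to affine-gap alignment only when
        # identity drops toward chance (indel-shifted windows).
        if ham >= 0.40:
            identities.append(ham)
        else:
            identities.append(_alignment_identity(frag, window.tobytes().decode()))
    if not identities:
        return 0.0, 0.0
    ani = 100.0 * float(np.mean(identities))
    af = len(identities) / len(frags)
    return ani, af


def _has_fragment(seqs: str | Sequence[str], fragment_len: int) -> bool:
    return max((len(p) for p in _pieces(seqs)), default=0) >= fragment_len


def bidirectional_best(
    query: str,
    query_seq: str | Sequence[str],
    candidate_refs: Mapping[str, "str | Sequence[str]"],
    criteria: SpeciesCriteria,
    expected_rep: str | None = None,
    self_exclude: frozenset[str] | set[str] = frozenset(),
    fragment_len: int = 3000,
    k_anchor: int = 15,
) -> AniResult:
    """Best bidirectional fragment-ANI hit over the candidate set.

    Per candidate, ANI and AF are each the maximum of the two directions;
    the best candidate has the highest ANI, ties broken by higher AF then
    accession.  Candidates in ``self_exclude`` are skipped.
    """
    best: tuple[float, float, str] | None = None
    for acc in sorted(candidate_refs):
        if acc in self_exclude:
            continue
        ref_seq = candidate_refs[acc]
        anis, afs = [], []
        if _has_fragment(query_seq, fragment_len) and _has_fragment(ref_seq, fragment_len):
            a1, f1 = fragment_ani(query_seq, ref_seq, fragment_len, k_anchor)
            a2, f2 = fragment_ani(ref_seq, query_seq, fragment_len, k_anchor)
            anis, afs = [a1, a2], [f1, f2]
        if not anis:
            continue
        ani, af = max(anis), max(afs)
        key = (ani, af, acc)
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
            (key[0], key[1]) == (best[0], best[1]) and acc < best[2]
        ):
            best = key
    if best is None:
        return AniResult(
            query=query,
            best_ref=None,
            ani=0.0,
            af=0.0,
            category="new_species",
            expected_rep=expected_rep,
        )
    ani, af, acc = best
    category = categorize(ani, af, acc, expected_rep, criteria)
    return AniResult(
        query=query,
        best_ref=acc,
        ani=ani,
        af=af,
        category=category,
        expected_rep=expected_rep,
    )


def categorize(
    ani: float,
    af: float,
    best_ref: str | None,
    expected_rep: str | None,
    criteria: SpeciesCriteria,
) -> str:
    """Three-way decision: same / changed / new species cluster."""
    meets = best_ref is not None and ani >= criteria.ani_min and af >= criteria.af_min
    if not meets:
        return "new_species"
    if best_ref == expected_rep:
        return "same_species"
    return "changed_species"


def classify_genome(
    query: str,
    query_seq: "str | Sequence[str]",
    ref_seqs: Mapping[str, "str | Sequence[str]"],
    ref_sketches: Mapping[str, MinHashSketch],
    rep_metadata: Mapping[str, TaxonomyString],
    expected_tax: TaxonomyString,
    expected_rep: str | None,
    criteria: SpeciesCriteria | None = None,
    params: MinHashParams | None = None,
    self_exclude: frozenset[str] | set[str] = frozenset(),
    fragment_len: int = 3000,
    context_min: int = 100,
) -> AniResult:
    """End-to-end classification of one query against a representative DB:
    MinHash prefilter union taxonomic context, then bidirectional best."""
    params = params or MinHashParams()
    criteria = criteria or SpeciesCriteria()
    qsketch = sketch(query_seq, params)
    near = prefilter_references(qsketch, ref_sketches, params)
    context = taxonomic_context(expected_tax, rep_metadata, context_min)
    candidates = {acc: ref_seqs[acc] for acc in set(near) | set(context)}
    return bidirectional_best(
        query,
        query_seq,
        candidates,
        criteria,
        expected_rep=expected_rep,
        self_exclude=self_exclude,
        fragment_len=fragment_len,
    )
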