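"""Taxonomy congruency scoring and MSA row substitution / column masking.

Congruency compares two classifications of the same genome from phylum to
genus, recording the highest-ranked incongruent name.  Tree inference itself
is out of scope: observed taxonomy strings are supplied by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import ColumnMask, TaxonomyString

#: Ranks scanned for congruency, shallow to deep.
CONGRUENCY_RANKS: tuple[str, ...] = ("p", "c", "o", "f", "g")


@dataclass(frozen=True)
class CongruencyResult:
    accession: str
    congruent: bool
    highest_incongruent_rank: str | None
    original: TaxonomyString
    observed: TaxonomyString


def compare_taxonomies(
    original: TaxonomyString,
    observed: TaxonomyString,
    accession: str = "",
) -> CongruencyResult:
    """Scan phylum to genus; the first named-rank mismatch is recorded.

    Ranks unnamed (or absent) in either string are skipped.  A domain
    mismatch is outside the phylum-genus scan and is reported with the
    sentinel rank code 'd' plus a warning.
    """
    orig_domain = original.named_at("d")
    obs_domain = observed.named_at("d")
    if orig_domain is not None and obs_domain is not None and orig_domain != obs_domain:
        warnings.warn(
            f"{accession or 'genome'}: domain mismatch "
            f"({orig_domain!r} vs {obs_domain!r})",
            stacklevel=2,
        )
        return CongruencyResult(accession, False, "d", original, observed)
    for code in CONGRUENCY_RANKS:
        a = original.named_at(code)
        b = observed.named_at(code)
        if a is None or b is None:
            continue
        if a != b:
            return CongruencyResult(accession, False, code, original, observed)
    return CongruencyResult(accession, True, None, original, observed)


# ---------------------------------------------------------------------------
# MSA handling.  An MSA is an ordered mapping accession -> aligned sequence.


def _check_rectangular(msa: Mapping[str, str]) -> int:
    widths = {len(seq) for seq in msa.values()}
    if len(widths) > 1:
        raise ValueError(f"ragged MSA: row widths {sorted(widths)}")
    return widths.pop() if widths else 0


def substitute_msa_rows(
    msa: Mapping[str, str], replacements: Mapping[str, str]
) -> dict[str, str]:
    """Replace rows in place by accession; all other rows are untouched."""
    width = _check_rectangular(msa)
    unknown = set(replacements) - set(msa)
    if unknown:
        raise ValueError(f"replacement accessions not in MSA: {sorted(unknown)}")
    for acc, seq in replacements.items():
        if len(seq) != width:
            raise ValueError(
                f"replacement for {acc!r} has {len(seq)} columns, MSA has {width}"
            )
    return {acc: replacements.get(acc, seq) for acc, seq in msa.items()}


def apply_mask(msa: Mapping[str, str], mask: ColumnMask) -> dict[str, str]:
    """Keep only the masked-in columns, preserving column order."""
    width = _check_rectangular(msa)
    if width != len(mask):
        raise ValueError(f"mask length {len(mask)} != MSA width {width}")
    keep = mask.keep
    return {
        acc: "".join(ch for ch, k in zip(seq, keep) if k)
        for acc, seq in msa.items()
    }


def mask_row(row: str, mask: ColumnMask) -> str:
    if len(row) != len(mask):
        raise ValueError(f"mask length {len(mask)} != row width {len(row)}")
    return "".join(ch for ch, k in zip(row, mask.keep) if k)


def concat_markers(
    marker_alignments: Mapping[str, str],
    marker_order: Sequence[tuple[str, int]],
    gap_char: str = "-",
) -> str:
    """Join per-marker aligned fragments in canonical marker order.

    ``marker_order`` lists (marker_id, column width).  Missing markers are
    filled with gap columns of that marker's width.
    """
    unknown = set(marker_alignments) - {m for m, _ in marker_order}
    if unknown:
        raise ValueError(f"markers not in canonical order list: {sorted(unknown)}")
    parts = []
    for marker_id, width in marker_order:
        frag = marker_alignments.get(marker_id)
        if frag is None:
            parts.append(gap_char * width)
        else:
            if len(frag) != width:
                raise ValueError(
                    f"marker {marker_id!r} fragment width {len(frag)} != {width}"
                )
            parts.append(frag)
    return "".join(parts)
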