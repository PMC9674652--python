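"""Complete enumeration and canonicalization of a deep indel mutagenesis (DIM) library.

A DIM library for a wild-type (WT) peptide of length L contains every single
amino-acid substitution, every single amino-acid insertion, every deletion
(single residues and contiguous internal multi-residue intervals), and every
truncation removing residues from one or both ends. Distinct mutation
specifications can produce the same peptide (deleting either of two adjacent
identical residues, for example), so the library is canonicalized: variants
are equivalence classes of specifications sharing one product sequence, each
assigned exactly one mutation class.

Coordinates are 1-based throughout; deletion intervals are inclusive.
An insertion at gap ``g`` places the new residue between WT residues ``g-1``
and ``g`` and is reported at the position the inserted residue occupies in
the mutant (an insertion between positions 1 and 2 sits at position 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .codons import DEFAULT_CODON_TABLE, min_nt_changes, reverse_translate_seq

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: 42-residue amyloid-beta peptide, the default WT for the atlas.
ABETA42 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

SUBSTITUTION = "substitution"
INSERTION = "insertion"
SINGLE_DELETION = "single_deletion"
MULTI_DELETION = "multi_deletion"
TRUNCATION = "truncation"
WT_CLASS = "wt"

#: precedence used when one product sequence is reachable from several
#: mutation classes: single-residue removals always win (deleting residue 1
#: or L is a single deletion, not a truncation), products identical to a
#: truncation product are truncations, the rest of the contiguous internal
#: removals are multi-residue deletions.
CLASS_PRECEDENCE = (SINGLE_DELETION, TRUNCATION, MULTI_DELETION, INSERTION, SUBSTITUTION)


class ProteinSequence(str):
    """An amino-acid sequence restricted to the 20 canonical letters."""

    def __new__(cls, seq: str) -> "ProteinSequence":
        seq = str(seq).strip().upper()
        if not seq:
            raise ValueError("protein sequence must be non-empty")
        bad = set(seq) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"non-canonical amino-acid letters: {sorted(bad)}")
        return super().__new__(cls, seq)

    @property
    def length(self) -> int:
        return len(self)


@dataclass(frozen=True, order=True)
class VariantSpec:
    """A symbolic mutation relative to the WT peptide.

    ``params`` per class:
      substitution    (position, new_aa)
      insertion       (gap,) + (inserted_aa,)   gap g = before WT residue g
      single_deletion (position,)
      multi_deletion  (start, end)              1-based inclusive
      truncation      (n_removed_nterm, n_removed_cterm)
    """

    mclass: str
    params: tuple

    def validate(self, wt: ProteinSequence) -> None:
        L = len(wt)
        c, p = self.mclass, self.params
        if c == SUBSTITUTION:
            pos, aa = p
            if not 1 <= pos <= L:
                raise ValueError(f"substitution position {pos} outside [1, {L}]")
            if aa not in AA_ALPHABET:
                raise ValueError(f"invalid amino acid {aa!r}")
            if aa == wt[pos - 1]:
                raise ValueError(f"substitution at {pos} must change the residue")
        elif c == INSERTION:
            gap, aa = p
            if not 1 <= gap <= L + 1:
                raise ValueError(f"insertion gap {gap} outside [1, {L + 1}]")
            if aa not in AA_ALPHABET:
                raise ValueError(f"invalid amino acid {aa!r}")
        elif c == SINGLE_DELETION:
            (pos,) = p
            if not 1 <= pos <= L:
                raise ValueError(f"deletion position {pos} outside [1, {L}]")
        elif c == MULTI_DELETION:
            s, e = p
            k = e - s + 1
            if not (2 <= s <= e <= L - 1):
                raise ValueError(f"internal deletion [{s}, {e}] must lie within [2, {L - 1}]")
            if not 2 <= k <= min(39, L - 3):
                raise ValueError(f"deletion length {k} outside [2, {min(39, L - 3)}]")
        elif c == TRUNCATION:
            a, b = p
            if a < 0 or b < 0 or not 2 <= a + b <= min(39, L - 3):
                raise ValueError(f"truncation ({a}, {b}) removes an invalid number of residues")
        elif c == WT_CLASS:
            pass
        else:
            raise ValueError(f"unknown mutation class {c!r}")

    def apply(self, wt: ProteinSequence) -> str:
        """Return the mutant peptide produced by this mutation."""
        c, p = self.mclass, self.params
        L = len(wt)
        if c == SUBSTITUTION:
            pos, aa = p
            return wt[: pos - 1] + aa + wt[pos:]
        if c == INSERTION:
            gap, aa = p
            return wt[: gap - 1] + aa + wt[gap - 1:]
        if c == SINGLE_DELETION:
            (pos,) = p
            return wt[: pos - 1] + wt[pos:]
        if c == MULTI_DELETION:
            s, e = p
            return wt[: s - 1] + wt[e:]
        if c == TRUNCATION:
            a, b = p
            return wt[a: L - b]
        if c == WT_CLASS:
            return str(wt)
        raise ValueError(f"unknown mutation class {c!r}")

    def removed_positions(self, wt: ProteinSequence) -> tuple[int, ...]:
        """WT positions removed by this mutation (empty for subs/insertions)."""
        L = len(wt)
        c, p = self.mclass, self.params
        if c == SINGLE_DELETION:
            return (p[0],)
        if c == MULTI_DELETION:
            return tuple(range(p[0], p[1] + 1))
        if c == TRUNCATION:
            a, b = p
            return tuple(range(1, a + 1)) + tuple(range(L - b + 1, L + 1))
        return ()

    def display_position(self, wt: ProteinSequence) -> int | None:
        """The single position the variant is reported at, where one exists.

        Substitutions and single deletions use the mutated WT position;
        insertions use the mutant-sequence index of the inserted residue,
        which equals the gap index. Interval mutations return None.
        """
        c = self.mclass
        if c in (SUBSTITUTION, SINGLE_DELETION):
            return self.params[0]
        if c == INSERTION:
            return self.params[0]
        return None

    def name(self, wt: ProteinSequence) -> str:
        c, p = self.mclass, self.params
        if c == SUBSTITUTION:
            pos, aa = p
            return f"{wt[pos - 1]}{pos}{aa}"
        if c == INSERTION:
            gap, aa = p
            return f"ins{gap}{aa}"
        if c == SINGLE_DELETION:
            (pos,) = p
            return f"{wt[pos - 1]}{pos}del"
        if c == MULTI_DELETION:
            s, e = p
            return f"del{s}-{e}"
        if c == TRUNCATION:
            a, b = p
            return f"trunc{a}-{b}"
        return "WT"


@dataclass
class DesignedVariant:
    """An equivalence class of mutation specs sharing one product sequence."""

    variant_id: str
    canonical_seq: str
    specs: tuple[VariantSpec, ...]
    assigned_class: str
    display_positions: tuple[int | None, ...]
    nt_seq: str = ""
    nt_min_changes: float = math.inf

    @property
    def is_wt(self) -> bool:
        return self.assigned_class == WT_CLASS


@dataclass
class DesignParams:
    """Knobs of the library design (defaults reproduce the full design space)."""

    gap_range: tuple[int, int] | None = None  # None = all L+1 gaps
    min_del_len: int = 1
    max_del_len: int = 39
    codon_table: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CODON_TABLE))
    wt_nt_seq: str | None = None  # derived from codon_table when None


@dataclass
class DesignedLibrary:
    wt: ProteinSequence
    variants: list[DesignedVariant]
    design_params: DesignParams

    def __post_init__(self) -> None:
        seqs = [v.canonical_seq for v in self.variants]
        if len(seqs) != len(set(seqs)):
            raise ValueError("canonical sequences must be unique across the library")

    def __iter__(self) -> Iterator[DesignedVariant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def wt_variant(self) -> DesignedVariant:
        return next(v for v in self.variants if v.is_wt)

    def by_id(self, variant_id: str) -> DesignedVariant:
        return self._id_index()[variant_id]

    def _id_index(self) -> dict[str, DesignedVariant]:
        if not hasattr(self, "_ids"):
            self._ids = {v.variant_id: v for v in self.variants}
        return self._ids

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.variants:
            if not v.is_wt:
                counts[v.assigned_class] = counts.get(v.assigned_class, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.variants:
            rows.append(
                {
                    "variant_id": v.variant_id,
                    "canonical_seq": v.canonical_seq,
                    "assigned_class": v.assigned_class,
                    "specs": ";".join(s.name(self.wt) for s in v.specs),
                    "display_positions": ";".join(
                        "" if p is None else str(p) for p in v.display_positions
                    ),
                    "nt_seq": v.nt_seq,
                    "nt_min_changes": v.nt_min_changes,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = []
        for v in self.variants:
            pos = ",".join("" if p is None else str(p) for p in v.display_positions)
            desc = f"{v.assigned_class}|{';'.join(s.name(self.wt) for s in v.specs)}|{pos}"
            records.append(SeqRecord(Seq(v.canonical_seq), id=v.variant_id, description=desc))
        seqio_write(records, path, "fasta")


def enumerate_substitutions(wt: ProteinSequence) -> list[VariantSpec]:
    """All 19·L single substitutions, position-major, amino acids alphabetical."""
    wt = ProteinSequence(wt)
    return [
        VariantSpec(SUBSTITUTION, (pos, aa))
        for pos in range(1, len(wt) + 1)
        for aa in AA_ALPHABET
        if aa != wt[pos - 1]
    ]


def enumerate_insertions(
    wt: ProteinSequence, gap_range: tuple[int, int] | None = None
) -> list[VariantSpec]:
    """All single insertions at every gap in ``gap_range`` (default: all L+1 gaps)."""
    wt = ProteinSequence(wt)
    L = len(wt)
    lo, hi = gap_range if gap_range is not None else (1, L + 1)
    if lo > hi:
        raise ValueError("empty insertion gap range")
    if lo < 1 or hi > L + 1:
        raise ValueError(f"gap range [{lo}, {hi}] outside [1, {L + 1}]")
    return [
        VariantSpec(INSERTION, (gap, aa))
        for gap in range(lo, hi + 1)
        for aa in AA_ALPHABET
    ]


def enumerate_deletions(
    wt: ProteinSequence, min_len: int = 1, max_len: int = 39
) -> list[VariantSpec]:
    """Single deletions at every position plus all internal multi-residue intervals.

    Internal intervals satisfy 2 <= start, end <= L-1; removals touching an
    end are the business of :func:`enumerate_truncations`.
    """
    wt = ProteinSequence(wt)
    L = len(wt)
    if not 1 <= min_len <= max_len <= L - 3:
        raise ValueError(f"deletion length bounds [{min_len}, {max_len}] invalid for L={L}")
    specs: list[VariantSpec] = []
    if min_len <= 1:
        specs.extend(VariantSpec(SINGLE_DELETION, (pos,)) for pos in range(1, L + 1))
    lo = max(2, min_len)
    for s in range(2, L):
        for e in range(s + lo - 2, L):
            if lo <= e - s + 1 <= max_len:
                specs.append(VariantSpec(MULTI_DELETION, (s, e)))
    return specs


def enumerate_truncations(wt: ProteinSequence) -> list[VariantSpec]:
    """All (a, b) end-removals with a+b in [2, min(39, L-3)] (min product length 3)."""
    wt = ProteinSequence(wt)
    L = len(wt)
    if L < 5:
        raise ValueError("truncation enumeration needs L >= 5")
    kmax = min(39, L - 3)
    return [
        VariantSpec(TRUNCATION, (a, k - a))
        for k in range(2, kmax + 1)
        for a in range(0, k + 1)
    ]


def canonicalize(spec: VariantSpec, wt: ProteinSequence) -> str:
    """The mutant peptide string produced by applying ``spec`` to ``wt``."""
    wt = ProteinSequence(wt)
    spec.validate(wt)
    return spec.apply(wt)


def _assign_class(specs: Iterable[VariantSpec]) -> str:
    present = {s.mclass for s in specs}
    for c in CLASS_PRECEDENCE:
        if c in present:
            return c
    raise RuntimeError("empty spec set")  # pragma: no cover


def build_library(
    wt: ProteinSequence | str, design_params: DesignParams | None = None
) -> DesignedLibrary:
    """Enumerate, canonicalize and annotate the complete DIM library for ``wt``.

    Specs are collapsed by product string; each unique product gets exactly one
    mutation class under the precedence single_deletion > truncation >
    multi_deletion (substitutions and insertions cannot collide with the other
    classes because their products have different lengths or edit structure).
    """
    wt = ProteinSequence(wt)
    params = design_params or DesignParams()

    specs: list[VariantSpec] = []
    specs += enumerate_substitutions(wt)
    specs += enumerate_insertions(wt, params.gap_range)
    specs += enumerate_deletions(
        wt, params.min_del_len, min(params.max_del_len, len(wt) - 3)
    )
    specs += enumerate_truncations(wt)

    by_product: dict[str, list[VariantSpec]] = {}
    for spec in specs:
        by_product.setdefault(spec.apply(wt), []).append(spec)
    if str(wt) in by_product:
        raise RuntimeError("a mutation spec unexpectedly reproduced the WT sequence")

    wt_nt = params.wt_nt_seq or reverse_translate_seq(wt, params.codon_table)

    variants: list[DesignedVariant] = [
        DesignedVariant(
            variant_id="WT",
            canonical_seq=str(wt),
            specs=(VariantSpec(WT_CLASS, ()),),
            assigned_class=WT_CLASS,
            display_positions=(None,),
            nt_seq=wt_nt,
            nt_min_changes=0.0,
        )
    ]

    class_rank = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}
    for product in sorted(by_product):
        group = by_product[product]
        assigned = _assign_class(group)
        # deterministic spec order: class precedence, then parameters
        group = sorted(group, key=lambda s: (class_rank[s.mclass], s.params))
        variants.append(
            DesignedVariant(
                variant_id=group[0].name(wt),
                canonical_seq=product,
                specs=tuple(group),
                assigned_class=assigned,
                display_positions=tuple(s.display_position(wt) for s in group),
                nt_seq=reverse_translate_seq(product, params.codon_table),
            )
        )

    # diff-stable ordering: class, then lead-spec parameters
    variants.sort(
        key=lambda v: (
            -1 if v.is_wt else class_rank[v.assigned_class],
            v.specs[0].params,
        )
    )

    _annotate_nt_changes(variants, wt, wt_nt, params.codon_table)
    return DesignedLibrary(wt=wt, variants=variants, design_params=params)


def _annotate_nt_changes(
    variants: list[DesignedVariant], wt: ProteinSequence, wt_nt: str, codon_table
) -> None:
    """Minimum nucleotide substitutions from the WT coding sequence.

    Defined (finite) only for amino-acid substitutions: the minimum Hamming
    distance between the WT codon and any sense codon of the target residue.
    Indel products are unreachable by substitution alone and carry infinity.
    """
    for v in variants:
        if v.assigned_class == SUBSTITUTION:
            pos, aa = v.specs[0].params
            wt_codon = wt_nt[3 * (pos - 1): 3 * pos]
            v.nt_min_changes = float(min_nt_changes(wt_codon, aa))
        elif v.is_wt:
            v.nt_min_changes = 0.0
        else:
            v.nt_min_changes = math.inf


def library_from_csv(path, wt: str | None = None) -> DesignedLibrary:
    """Rehydrate a :class:`DesignedLibrary` from its CSV export."""
    df = pd.read_csv(path, keep_default_na=False)
    wt_row = df[df["assigned_class"] == WT_CLASS]
    if wt_row.empty and wt is None:
        raise ValueError("library CSV lacks a WT row and no WT sequence was given")
    wt_seq = ProteinSequence(wt if wt is not None else wt_row.iloc[0]["canonical_seq"])
    variants = []
    for _, row in df.iterrows():
        specs = tuple(
            _parse_spec_name(name, wt_seq) for name in str(row["specs"]).split(";") if name
        )
        disp = tuple(
            None if p == "" else int(p) for p in str(row["display_positions"]).split(";")
        ) or (None,)
        variants.append(
            DesignedVariant(
                variant_id=row["variant_id"],
                canonical_seq=row["canonical_seq"],
                specs=specs or (VariantSpec(WT_CLASS, ()),),
                assigned_class=row["assigned_class"],
                display_positions=disp,
                nt_seq=str(row.get("nt_seq", "")),
                nt_min_changes=float(row["nt_min_changes"]),
            )
        )
    return DesignedLibrary(wt=wt_seq, variants=variants, design_params=DesignParams())


def _parse_spec_name(name: str, wt: ProteinSequence) -> VariantSpec:
    if name == "WT":
        return VariantSpec(WT_CLASS, ())
    if name.startswith("ins"):
        return VariantSpec(INSERTION, (int(name[3:-1]), name[-1]))
    if name.startswith("del"):
        s, e = name[3:].split("-")
        return VariantSpec(MULTI_DELETION, (int(s), int(e)))
    if name.startswith("trunc"):
        a, b = name[5:].split("-")
        return VariantSpec(TRUNCATION, (int(a), int(b)))
    if name.endswith("del"):
        return VariantSpec(SINGLE_DELETION, (int(name[1:-3]),))
    return VariantSpec(SUBSTITUTION, (int(name[1:-1]), name[-1]))
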