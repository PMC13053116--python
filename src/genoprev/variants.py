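"""Normalized genomic variant identity.

All downstream joins (deduplication across ClinVar / HGMD / gnomAD pLoF
lists, frequency lookup) key on a normalized ``(contig, pos, ref, alt)``
tuple on a single genome build. HGVS strings are carried as provenance
metadata only and are never used as a join key.

Coordinates are 1-based and fully closed; indels use the VCF anchor-base
convention on the forward genomic strand. Normalization means the usual
left-align / trim procedure: no shared suffix between the alleles, a shared
prefix only as the single anchor base of an indel, and the representation
moved to its leftmost equivalent position in the reference context.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

_ALLELE_CHARS = frozenset("ACGT")

DEFAULT_BUILD = "GRCh38"


class VariantError(ValueError):
    """Raised for malformed variant representations."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a sequence variant: contig, 1-based position, alleles, build.

    Alleles must be non-empty uppercase A/C/G/T strings and must differ;
    minimality/left-alignment is established by :func:`normalize_variant`,
    not by construction, because raw source rows may be unnormalized.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    build: str = DEFAULT_BUILD

    def __post_init__(self) -> None:
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise VariantError(
                    f"{self.contig}:{self.pos} {self.ref}>{self.alt}: "
                    f"{name} allele {allele!r} is not a non-empty A/C/G/T string"
                )
        if self.ref == self.alt:
            raise VariantError(
                f"{self.contig}:{self.pos}: ref equals alt ({self.ref!r}); not a variant"
            )
        if self.pos < 1:
            raise VariantError(f"{self.contig}:{self.pos}: position must be >= 1")

    def __str__(self) -> str:  # pragma: no cover - display convenience
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class ReferenceContext:
    """A slice of reference sequence anchored at a 1-based position.

    ``seq[0]`` is the base at position ``start`` on ``contig``. Used to
    left-align indels; a context spanning the repetitive tract around the
    variant suffices.
    """

    seq: str
    start: int
    contig: str | None = None

    def base(self, pos: int) -> str:
        off = pos - self.start
        if off < 0 or off >= len(self.seq):
            raise VariantError(
                f"position {pos} outside reference context [{self.start}, "
                f"{self.start + len(self.seq) - 1}]"
            )
        return self.seq[off]

    def slice(self, pos: int, length: int) -> str:
        return "".join(self.base(pos + i) for i in range(length))


def normalize_variant(
    raw: VariantKey, context: ReferenceContext | None = None
) -> VariantKey:
    """Return the left-aligned, minimal representation of ``raw``.

    Right-trims the shared allele suffix, left-extends through the reference
    context when trimming would empty an allele (this is what walks an indel
    leftward through a repeat tract), then trims the shared prefix down to
    the single anchor base. Idempotent: normalizing an already-normalized
    key returns it unchanged.

    Without a ``context`` only suffix/prefix trimming is performed, which is
    exact for substitutions; indels inside repeat tracts additionally need
    the context to reach their leftmost position. When a context is given
    the ref allele is checked against it.
    """
    pos, ref, alt = raw.pos, raw.ref, raw.alt
    if context is not None and context.slice(pos, len(ref)) != ref:
        raise VariantError(
            f"{raw}: ref allele does not match reference context "
            f"({context.slice(pos, len(ref))!r} at {pos})"
        )

    while ref[-1] == alt[-1]:
        if len(ref) == 1 or len(alt) == 1:
            if context is None:
                break
            prev = context.base(pos - 1)
            ref, alt, pos = prev + ref, prev + alt, pos - 1
        ref, alt = ref[:-1], alt[:-1]

    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1

    if (pos, ref, alt) == (raw.pos, raw.ref, raw.alt):
        return raw
    return replace(raw, pos=pos, ref=ref, alt=alt)
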