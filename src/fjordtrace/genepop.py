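"""Reader and writer for the GENEPOP genotype text format (4.x conventions).

Layout: a free-text title line, locus names (one per line, or one line of
comma-separated names), then POP-delimited sample blocks.  Each sample line
is ``<id> ,  <genotype> <genotype> ...`` with 2- or 3-digit allele codes
concatenated per diploid call; ``00``/``000`` denotes a missing allele.
By convention here the first two POP blocks are the reference populations
and any further blocks are study individuals.
"""

from __future__ import annotations

import re
from pathlib import Path

from .genetics import Call, ReferencePanel, SnpGenotype

__all__ = ["read_genepop", "write_genepop", "GenepopError"]


class GenepopError(ValueError):
    """Structural or parse error in a GENEPOP file, naming the line."""


_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def _split_call(token: str, lineno: int) -> Call:
    if len(token) == 4:
        width = 2
    elif len(token) == 6:
        width = 3
    else:
        raise GenepopError(
            f"line {lineno}: genotype token {token!r} is neither 4 nor 6 digits"
        )
    if not token.isdigit():
        raise GenepopError(f"line {lineno}: non-numeric genotype token {token!r}")
    a, b = token[:width], token[width:]
    missing = "0" * width
    if a == missing or b == missing:
        return None
    return (a, b)


def read_genepop(
    path: str | Path,
    reference_pops: tuple[str, str] = ("FJ", "NS"),
) -> tuple[ReferencePanel, list[SnpGenotype]]:
    """Parse a GENEPOP file into a reference panel plus study genotypes.

    The first two POP blocks become the reference populations (named by
    ``reference_pops``, in file order); individuals from any later block are
    returned as study genotypes.  The allele registry per locus spans all
    blocks, so the panel can score study-only alleles (with zero reference
    count).
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopError("empty file")
    # locus names: everything between the title line and the first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i].strip()):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if not loci:
        raise GenepopError("no locus names before the first POP line")
    if i >= len(lines):
        raise GenepopError("no POP blocks found")

    blocks: list[list[tuple[str, tuple[Call, ...]]]] = []
    current: list[tuple[str, tuple[Call, ...]]] | None = None
    for lineno0, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if _POP_RE.match(line):
            current = []
            blocks.append(current)
            continue
        if current is None:
            raise GenepopError(f"line {lineno0}: sample before any POP line")
        if "," in line:
            ind_id, geno_part = line.split(",", 1)
        else:
            # tolerate a missing comma: first token is the id
            ind_id, _, geno_part = line.partition(" ")
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise GenepopError(
                f"line {lineno0}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        calls = tuple(_split_call(tok, lineno0) for tok in tokens)
        current.append((ind_id.strip(), calls))

    if len(blocks) < 2:
        raise GenepopError(f"found {len(blocks)} POP block(s); need at least 2")

    counts: dict[str, list[dict[str, int]]] = {
        pop: [dict() for _ in loci] for pop in reference_pops
    }
    for pop, block in zip(reference_pops, blocks[:2]):
        for _ind, calls in block:
            for li, call in enumerate(calls):
                if call is None:
                    continue
                for allele in call:
                    counts[pop][li][allele] = counts[pop][li].get(allele, 0) + 1

    study = [
        SnpGenotype(individual_id=ind, calls=calls)
        for block in blocks[2:]
        for ind, calls in block
    ]
    panel = ReferencePanel(
        loci=tuple(loci), populations=tuple(reference_pops), counts=counts
    )
    panel.register_alleles(study)
    # make sure study alleles have registry entries in reference counts too
    return panel, study


def write_genepop(
    path: str | Path,
    loci: tuple[str, ...],
    reference_blocks: dict[str, list[SnpGenotype]],
    study: list[SnpGenotype],
    title: str = "fjordtrace simulated genotypes",
    allele_width: int = 2,
) -> None:
    """Write reference POP blocks followed by one study POP block."""
    missing = "0" * allele_width

    def fmt(g: SnpGenotype) -> str:
        toks = []
        for call in g.calls:
            if call is None:
                toks.append(missing * 2)
            else:
                toks.append(call[0].zfill(allele_width) + call[1].zfill(allele_width))
        return f"{g.individual_id} ,  " + " ".join(toks)

    out = [title]
    out.extend(loci)
    for _pop, block in reference_blocks.items():
        out.append("POP")
        out.extend(fmt(g) for g in block)
    out.append("POP")
    out.extend(fmt(g) for g in study)
    Path(path).write_text("\n".join(out) + "\n")
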