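"""Parser for samtools-style mpileup text, yielding per-sample allele counts
at panel SNPs.

Only the textual pileup format is consumed here (the upstream mapping
that produces it is out of scope).  Base-string grammar handled:

* ``.`` / ``,`` — match to the reference base (forward/reverse strand);
* ``ACGTacgt`` — mismatching base;
* ``^`` + mapping-quality character — read start, both characters skipped;
* ``$`` — read end, skipped;
* ``+n``/``-n`` followed by n inserted/deleted bases — skipped entirely
  (the anchoring base has already been counted);
* ``*`` — deletion placeholder, ``<``/``>`` — reference skip: counted as
  "other" coverage;
* ``N``/``n`` — ambiguous base, counted as "other".

Counts are strand-collapsed.  Panel loci never seen in the stream are
emitted with zero counts so downstream callers see an explicit record.
"""

from __future__ import annotations

from typing import Iterable, Sequence, TextIO

import pandas as pd

from .genotyping import PanelLocus


class MpileupError(ValueError):
    """Malformed pileup input; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"mpileup line {lineno}: {message}")
        self.lineno = lineno


def count_bases(bases: str, ref: str, lineno: int = 0) -> dict[str, int]:
    """Tally a pileup base string into per-base counts plus 'other'."""
    counts = {"A": 0, "C": 0, "G": 0, "T": 0, "other": 0}
    ref = ref.upper()
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise MpileupError(lineno, "dangling '^' in base string")
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise MpileupError(lineno, f"indel marker {c!r} without length")
            length = int(bases[i + 1 : j])
            i = j + length
            if i > n:
                raise MpileupError(lineno, "indel span exceeds base string")
            continue
        if c in ".,":
            if ref in counts:
                counts[ref] += 1
            else:
                counts["other"] += 1
        elif c.upper() in "ACGT":
            counts[c.upper()] += 1
        elif c in "*<>Nn":
            counts["other"] += 1
        else:
            raise MpileupError(lineno, f"unexpected symbol {c!r} in base string")
        i += 1
    return counts


def parse_mpileup(
    stream: TextIO | Iterable[str],
    panel: Sequence[PanelLocus],
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Parse pileup text into an allele-count table restricted to the panel.

    Parameters
    ----------
    stream : text stream or iterable of lines
        Pileup lines: ``chrom  pos  ref  depth  bases  quals`` with the
        last three columns repeated per sample.
    panel : sequence of PanelLocus
        Only these (chrom, pos) positions are emitted.
    sample_ids : optional
        Names for the sample columns; defaults to S1, S2, ...

    Returns
    -------
    DataFrame with ``sample_id, chrom, pos, n_A, n_L, n_other`` including
    zero-count records for panel positions absent from the stream.
    """
    by_pos = {(loc.chrom, loc.pos): loc for loc in panel}
    rows: list[tuple] = []
    seen: set[tuple[str, int]] = set()
    n_samples: int | None = None

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6 or (len(fields) - 3) % 3 != 0:
            raise MpileupError(lineno, f"expected 3 + 3k columns, got {len(fields)}")
        chrom, pos_s, ref = fields[0], fields[1], fields[2]
        try:
            pos = int(pos_s)
        except ValueError:
            raise MpileupError(lineno, f"non-integer position {pos_s!r}") from None
        k = (len(fields) - 3) // 3
        if n_samples is None:
            n_samples = k
            if sample_ids is not None and len(sample_ids) != k:
                raise MpileupError(
                    lineno, f"{len(sample_ids)} sample ids given but {k} sample columns"
                )
        elif k != n_samples:
            raise MpileupError(lineno, "inconsistent sample column count")

        locus = by_pos.get((chrom, pos))
        if locus is None:
            continue
        seen.add((chrom, pos))
        for s in range(k):
            depth_s, bases = fields[3 + 3 * s], fields[4 + 3 * s]
            try:
                int(depth_s)
            except ValueError:
                raise MpileupError(lineno, f"non-integer depth {depth_s!r}") from None
            counts = count_bases(bases, ref, lineno)
            total = sum(counts.values())
            n_a = counts[locus.allele_A]
            n_l = counts[locus.allele_L]
            name = sample_ids[s] if sample_ids is not None else f"S{s + 1}"
            rows.append((name, chrom, pos, n_a, n_l, total - n_a - n_l))

    names = (
        list(sample_ids)
        if sample_ids is not None
        else [f"S{s + 1}" for s in range(n_samples or 0)]
    )
    for loc in panel:
        if (loc.chrom, loc.pos) not in seen:
            for name in names:
                rows.append((name, loc.chrom, loc.pos, 0, 0, 0))

    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "n_A", "n_L", "n_other"])
    return df.sort_values(["chrom", "pos", "sample_id"], kind="stable").reset_index(drop=True)
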