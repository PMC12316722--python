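"""Synthetic reference genome for ring-minichromosome simulations.

The toy world is a single chromosome carrying a "mini region": the scaled
analog of the 6 Mb pericentromeric block of Arabidopsis chromosome 1 from
which the circular minichromosome derives.  All defaults are the real
coordinates shrunk by a single linear factor (:data:`SCALE_FACTOR`): the
mini region 13-19 Mb maps to 1.3-1.9 Mb, the CENH3-defined centromere
15-17 Mb to 1.5-1.7 Mb, and the ~1.3 Mb internal deletion 16-17.3 Mb to
1.6-1.73 Mb, on a 2 Mb chromosome.

The reference carries gene and repeat tracks with deliberate contrast
(repeats enriched, genes depleted inside the centromere analog) so that
breakpoint feature-enrichment statistics have signal to detect, plus a
table of diagnostic SNPs distinguishing the mini haplotype from the
recombinant background it segregates in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import Interval, merge_intervals

#: Linear shrink applied to every published coordinate.
SCALE_FACTOR = 10

#: Default toy chromosome name and length (2 Mb).
DEFAULT_CHROM = "Chr1"
DEFAULT_LENGTH = 2_000_000

#: Scaled analog of the mini source region (13-19 Mb), 1-based inclusive.
DEFAULT_MINI_REGION: Interval = (1_300_001, 1_900_000)
#: Scaled analog of the CENH3 centromere (15-17 Mb).
DEFAULT_CENTROMERE: Interval = (1_500_001, 1_700_000)
#: Scaled analog of the ~1.3 Mb internal deletion (16-17.3 Mb).
DEFAULT_DELETION: Interval = (1_600_001, 1_730_000)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ReferenceBundle:
    """A toy reference genome plus the annotation the pipeline consumes.

    Attributes
    ----------
    sequences
        Chromosome name -> uppercase base string.
    mini_region, centromere_analog
        1-based inclusive intervals on ``mini_chrom``.
    gene_intervals, repeat_intervals
        Lists of ``(chrom, start, end)``, 1-based inclusive, non-overlapping
        within each track.
    snp_table
        List of ``(pos, background_allele, mini_allele)`` on ``mini_chrom``;
        the reference sequence carries the background allele.
    """

    sequences: dict[str, str]
    mini_chrom: str
    mini_region: Interval
    centromere_analog: Interval
    gene_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    repeat_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    snp_table: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = len(self.sequences[self.mini_chrom])
        mr, cen = self.mini_region, self.centromere_analog
        if not (1 <= mr[0] <= mr[1] <= L):
            raise ValueError(f"mini_region {mr} outside chromosome bounds 1..{L}")
        if not (mr[0] <= cen[0] <= cen[1] <= mr[1]):
            raise ValueError(f"centromere_analog {cen} not inside mini_region {mr}")
        for chrom, s, e in self.gene_intervals + self.repeat_intervals:
            if not (1 <= s <= e <= len(self.sequences[chrom])):
                raise ValueError(f"feature interval ({chrom},{s},{e}) out of bounds")
        for pos, bg, mini in self.snp_table:
            if bg == mini:
                raise ValueError(f"SNP at {pos} has identical alleles {bg!r}")

    def feature_track(self, name: str, chrom: str | None = None) -> list[Interval]:
        """Merged intervals of a track ('gene' or 'repeat') on one chromosome."""
        chrom = chrom or self.mini_chrom
        track = self.gene_intervals if name == "gene" else self.repeat_intervals
        return merge_intervals((s, e) for c, s, e in track if c == chrom)


def _place_features(
    rng: np.random.Generator,
    region: Interval,
    fraction: float,
    mean_len: float,
) -> list[Interval]:
    """Tile ``region`` with alternating gaps/features hitting ``fraction``.

    Feature lengths are gamma (shape 4, mean ``mean_len``); each gap is
    exponential around the length that would bring the running covered
    fraction back to the request, so the realized fraction tracks the
    request closely even in short regions.
    """
    if fraction <= 0:
        return []
    gap_mean = mean_len * (1.0 - fraction) / fraction
    out: list[Interval] = []
    covered = 0
    pos = region[0] + int(rng.exponential(gap_mean / 2)) if gap_mean > 0 else region[0]
    while pos <= region[1]:
        length = max(50, int(rng.gamma(4.0, mean_len / 4.0)))
        end = min(pos + length - 1, region[1])
        out.append((pos, end))
        covered += end - pos + 1
        consumed = end + 1 - region[0]
        # drift-correcting gap: on average restores covered/consumed == fraction
        deficit = max(1.0, covered / fraction - consumed)
        gap = max(1, int(deficit * rng.uniform(0.5, 1.5)))
        pos = end + 1 + gap
    return out


def generate_reference(
    length: int = DEFAULT_LENGTH,
    mini_region: Interval = DEFAULT_MINI_REGION,
    centromere_analog: Interval | None = None,
    *,
    seed: int,
    chrom: str = DEFAULT_CHROM,
    gene_fraction: float = 0.35,
    gene_fraction_centromere: float = 0.05,
    repeat_fraction: float = 0.10,
    repeat_fraction_centromere: float = 0.60,
    feature_mean_len: float = 1_500.0,
    snp_density: float = 1 / 500,
) -> ReferenceBundle:
    """Generate a deterministic toy reference with annotation and SNPs.

    The centromere analog gets its own gene/repeat fractions so that genes
    are depleted and repeats enriched there, mirroring real pericentromeric
    annotation contrast.  ``snp_density`` is diagnostic SNPs per base over
    the whole chromosome (default one per 500 bp, an ecotype-cross scale).
    """
    if centromere_analog is None:
        span = mini_region[1] - mini_region[0] + 1
        centromere_analog = (
            mini_region[0] + span // 3,
            mini_region[1] - span // 3,
        )
    if length < mini_region[1]:
        raise ValueError(
            f"mini_region {mini_region} extends past chromosome length {length}"
        )
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length).tobytes().decode()

    cen = centromere_analog
    arms = [(1, cen[0] - 1), (cen[1] + 1, length)]

    genes: list[tuple[str, int, int]] = []
    repeats: list[tuple[str, int, int]] = []
    for region, gf, rf in [(cen, gene_fraction_centromere, repeat_fraction_centromere)] + [
        (arm, gene_fraction, repeat_fraction) for arm in arms if arm[0] <= arm[1]
    ]:
        genes += [(chrom, s, e) for s, e in _place_features(rng, region, gf, feature_mean_len)]
        repeats += [(chrom, s, e) for s, e in _place_features(rng, region, rf, feature_mean_len)]
    genes.sort(key=lambda t: t[1])
    repeats.sort(key=lambda t: t[1])

    n_snps = int(round(length * snp_density))
    positions = np.sort(rng.choice(np.arange(1, length + 1), size=n_snps, replace=False))
    snp_table: list[tuple[int, str, str]] = []
    for pos in positions:
        bg = seq[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != bg])
        snp_table.append((int(pos), bg, str(alt)))

    return ReferenceBundle(
        sequences={chrom: seq},
        mini_chrom=chrom,
        mini_region=mini_region,
        centromere_analog=centromere_analog,
        gene_intervals=genes,
        repeat_intervals=repeats,
        snp_table=snp_table,
    )
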