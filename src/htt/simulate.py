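"""Synthetic-data generator for end-to-end testing of the HT pipeline.

Builds diverging genome pairs, plants LTR-retrotransposon insertions with
LTR/TSD structure, amplifies copies after the transfer, and shreds genomes
into single-end reads, so every downstream stage can be exercised without
any external data.

The mutation model is substitution-only by default (an ``indel_rate``
parameter exists but defaults to 0), which keeps identity arithmetic exact:
``mutate(s, d)`` realizes exactly ``round(d/100 * len(s))`` substitutions at
distinct positions, so the global identity of the mutated copy is
``100 - d`` percent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .seqio import Interval, SeqRecord, decode, encode, revcomp

__all__ = ["SimConfig", "HTScenario", "make_te", "insert_te", "mutate", "shred",
           "build_ht_scenario", "build_vertical_scenario", "random_dna"]

# Deterministic reverse codon table: amino acid -> sorted list of codons.
_AA_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _AA_CODONS.setdefault(_aa, []).append(_codon)

# Ordered internal domains of a canonical LTR-retrotransposon and the lengths
# (aa) of the synthetic consensus proteins planted by make_te.
DOMAIN_ORDER = ("gag", "AP", "IN", "RT", "RH")
DOMAIN_AA_LEN = {"gag": 100, "AP": 40, "IN": 80, "RT": 180, "RH": 60}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _synthetic_domain_consensus() -> dict[str, str]:
    """Fixed synthetic amino-acid consensus for each of the five domains.

    These are synthetic stand-ins for curated domain models; the RT
    consensus carries the conserved YXDD catalytic motif (as YVDD) at its
    center, as real retroviral/retrotransposon RTs do.
    """
    rng = np.random.default_rng(20210508)
    cons = {}
    for name in DOMAIN_ORDER:
        length = DOMAIN_AA_LEN[name]
        aa = "".join(rng.choice(list(_AA20), size=length))
        if name == "RT":
            mid = length // 2
            aa = aa[:mid] + "YVDD" + aa[mid + 4:]
        cons[name] = aa
    return cons


DOMAIN_CONSENSUS = _synthetic_domain_consensus()


def random_dna(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def _encode_protein(aa_seq: str, rng: np.random.Generator) -> str:
    """DNA encoding of a protein with codons drawn uniformly per position."""
    return "".join(
        _AA_CODONS[aa][rng.integers(0, len(_AA_CODONS[aa]))] for aa in aa_seq
    )


@dataclass
class SimConfig:
    """Study conditions for one simulated HT scenario.

    Defaults mirror the survey design the pipeline was built for: ~2.3x
    single-end 150-bp sample sequencing of the donor, a vertical divergence
    of 14% between donor and recipient backgrounds (86% orthologous
    identity), a recent transfer at 1.5% divergence, and two post-HT
    amplified copies each carrying an extra 0.5% of substitutions.
    """

    seed: int = 0
    genome_len: int = 100_000
    vertical_divergence: float = 14.0
    ht_divergence: float = 1.5
    te_len: int = 5000
    ltr_len: int = 300
    tsd_len: int = 5
    n_amplified_copies: int = 2
    amplified_divergence: float = 0.5
    read_len: int = 151
    read_len_min: int | None = 100
    trimmed_fraction: float = 0.4
    coverage: float = 2.3
    indel_rate: float = 0.0
    n_cds: int = 40
    cds_len: int = 1000

    def __post_init__(self) -> None:
        for d in (self.vertical_divergence, self.ht_divergence, self.amplified_divergence):
            if not 0.0 <= d <= 100.0:
                raise ValueError("divergences must be in [0, 100]")
        if self.ltr_len * 2 >= self.te_len:
            raise ValueError("ltr_len * 2 must be < te_len")
        if not 4 <= self.tsd_len <= 6 and self.tsd_len != 0:
            raise ValueError("tsd_len must be 0 or in [4, 6]")
        if self.n_amplified_copies < 0:
            raise ValueError("n_amplified_copies must be >= 0")


@dataclass
class HTScenario:
    """A planted-transfer fixture with exact ground truth."""

    config: SimConfig
    donor_genome: SeqRecord
    recipient_genome: SeqRecord
    donor_reads: list[SeqRecord]
    truth: list[Interval]
    te: SeqRecord
    te_annotations: list[Interval]
    donor_te_interval: Interval
    cds: list[SeqRecord]


def make_te(te_len: int, ltr_len: int, seed: int) -> tuple[SeqRecord, list[Interval]]:
    """Build a structurally canonical LTR-retrotransposon.

    element = LTR + internal + LTR with both LTRs identical at creation,
    each beginning ``TG`` and ending ``CA``.  The internal region carries
    the five ordered coding domains (gag, AP, IN, RT, RH) as DNA encoding
    the synthetic consensus proteins, separated by random spacers.
    """
    if ltr_len < 10:
        raise ValueError("ltr_len must be >= 10")
    rng = np.random.default_rng([seed, 101])
    internal_len = te_len - 2 * ltr_len
    domain_dna = {
        name: _encode_protein(DOMAIN_CONSENSUS[name], rng) for name in DOMAIN_ORDER
    }
    coding_len = sum(len(s) for s in domain_dna.values())
    n_spacers = len(DOMAIN_ORDER) + 1
    spare = internal_len - coding_len
    if spare < n_spacers:
        raise ValueError(
            f"te_len {te_len} too small: internal region must hold {coding_len} bp "
            f"of domains plus spacers"
        )
    spacer_len = spare // n_spacers
    ltr = "TG" + random_dna(ltr_len - 4, rng) + "CA"

    parts = [ltr]
    intervals = []
    pos = ltr_len + 1
    for i, name in enumerate(DOMAIN_ORDER):
        pad = spacer_len if i > 0 else spare - spacer_len * (n_spacers - 1)
        parts.append(random_dna(pad, rng))
        pos += pad
        parts.append(domain_dna[name])
        intervals.append(
            Interval("te", pos, pos + len(domain_dna[name]) - 1, "domain", name)
        )
        pos += len(domain_dna[name])
    parts.append(random_dna(te_len - ltr_len - (pos - 1), rng))
    parts.append(ltr)
    seq = "".join(parts)
    assert len(seq) == te_len
    intervals = (
        [Interval("te", 1, te_len, "TE", "element"),
         Interval("te", 1, ltr_len, "LTR", "LTR5")]
        + intervals
        + [Interval("te", te_len - ltr_len + 1, te_len, "LTR", "LTR3")]
    )
    return SeqRecord(id="te", seq=seq), intervals


def insert_te(
    genome: SeqRecord,
    te: SeqRecord,
    pos: int,
    tsd_len: int,
    seed: int = 0,
) -> tuple[SeqRecord, Interval]:
    """Insert an element at ``pos`` duplicating the target site.

    The ``tsd_len`` bases at ``[pos, pos + tsd_len - 1]`` end up flanking
    the element on both sides; output length = input + len(te) + tsd_len.
    Returns the new genome and the element interval in its coordinates.
    """
    if not 1 <= pos <= len(genome):
        raise ValueError(f"pos {pos} outside genome of length {len(genome)}")
    if tsd_len < 0:
        raise ValueError("tsd_len must be >= 0")
    if pos + tsd_len - 1 > len(genome):
        raise ValueError("insertion site within tsd_len of the contig end")
    g = genome.seq
    new_seq = g[: pos - 1 + tsd_len] + te.seq + g[pos - 1:]
    element = Interval(genome.id, pos + tsd_len, pos + tsd_len + len(te) - 1, "TE", te.id)
    return SeqRecord(id=genome.id, seq=new_seq, taxon=genome.taxon), element


def mutate(
    seq: SeqRecord | str,
    divergence_pct: float,
    seed: int,
    indel_rate: float = 0.0,
) -> SeqRecord:
    """Substitute exactly ``round(divergence_pct/100 * len)`` positions.

    Positions are drawn without replacement and every substituted base
    differs from the original.  With ``indel_rate`` > 0 (percent of
    positions), single-base insertions and deletions are additionally
    applied after the substitutions.
    """
    if not 0.0 <= divergence_pct <= 100.0:
        raise ValueError("divergence_pct must be in [0, 100]")
    rec = seq if isinstance(seq, SeqRecord) else SeqRecord(id="seq", seq=seq)
    rng = np.random.default_rng([seed, 211])
    codes = encode(rec.seq).copy()
    n_sub = round(divergence_pct / 100.0 * len(codes))
    if n_sub:
        positions = rng.choice(len(codes), size=n_sub, replace=False)
        shifts = rng.integers(1, 4, size=n_sub).astype(np.uint8)
        orig = codes[positions]
        new = (orig + shifts) % 4
        # original N positions get a uniform ACGT draw
        n_mask = orig == 4
        if n_mask.any():
            new[n_mask] = rng.integers(0, 4, size=int(n_mask.sum()))
        codes[positions] = new
    out = decode(codes)
    if indel_rate > 0:
        n_indel = round(indel_rate / 100.0 * len(out))
        chars = list(out)
        for _ in range(n_indel):
            p = int(rng.integers(0, len(chars)))
            if rng.random() < 0.5:
                chars.insert(p, "ACGT"[rng.integers(0, 4)])
            else:
                del chars[p]
        out = "".join(chars)
    return SeqRecord(id=rec.id, seq=out, taxon=rec.taxon)


def shred(
    genome: SeqRecord,
    read_len: int,
    coverage: float,
    seed: int,
    read_len_min: int | None = None,
    trimmed_fraction: float = 0.4,
) -> list[SeqRecord]:
    """Shotgun-shred a genome into single-end reads.

    With a fixed read length, ``round(coverage * len / read_len)`` reads
    with uniform start positions; each read comes from either strand with
    probability 0.5 (minus-strand reads are reverse-complemented).  With
    ``read_len_min`` set, a ``trimmed_fraction`` of reads is
    quality-trimmed to a uniform length in ``[read_len_min, read_len)``
    while the rest stay full length, and the read count targets
    ``coverage`` at the mean length.
    """
    if read_len > len(genome):
        raise ValueError("read_len exceeds genome length")
    rng = np.random.default_rng([seed, 307])
    if read_len_min is None:
        lengths = None
        n_reads = round(coverage * len(genome) / read_len)
    else:
        if not 1 <= read_len_min <= read_len:
            raise ValueError("read_len_min must be in [1, read_len]")
        if not 0.0 <= trimmed_fraction <= 1.0:
            raise ValueError("trimmed_fraction must be in [0, 1]")
        mean_len = (
            (1 - trimmed_fraction) * read_len
            + trimmed_fraction * (read_len_min + read_len - 1) / 2.0
        )
        n_reads = round(coverage * len(genome) / mean_len)
        lengths = np.full(n_reads, read_len)
        trimmed = rng.random(n_reads) < trimmed_fraction
        lengths[trimmed] = rng.integers(
            read_len_min, read_len, size=int(trimmed.sum())
        )
    starts = rng.integers(0, len(genome) - read_len + 1, size=n_reads)
    flip = rng.random(n_reads) < 0.5
    reads = []
    for i, (s, rc) in enumerate(zip(starts, flip)):
        L = read_len if lengths is None else int(lengths[i])
        frag = genome.seq[s: s + L]
        if rc:
            frag = revcomp(frag)
        reads.append(
            SeqRecord(id=f"{genome.id}_r{i:06d}", seq=frag, taxon=genome.taxon)
        )
    return reads


def _pick_positions(
    rng: np.random.Generator,
    genome_len: int,
    n: int,
    min_gap: int,
    margin: int,
) -> list[int]:
    """n insertion positions with pairwise spacing >= min_gap."""
    for _ in range(1000):
        pos = np.sort(rng.integers(margin, genome_len - margin, size=n))
        if n == 1 or np.all(np.diff(pos) >= min_gap):
            return [int(p) for p in pos]
    raise RuntimeError("could not place insertions; genome too small for config")


def build_ht_scenario(config: SimConfig) -> HTScenario:
    """Compose a full planted-transfer fixture.

    The donor genome is the ancestral background carrying the source
    element; the recipient background diverges from it by
    ``vertical_divergence`` (so orthologous identity is exactly
    ``100 - vertical_divergence``).  One element copy crosses at
    ``ht_divergence`` and is amplified ``n_amplified_copies`` times, each
    amplified copy carrying ``amplified_divergence`` extra substitutions.
    Truth intervals are exact element coordinates on the recipient.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 401])
    background = SeqRecord(
        id="donor_genome", seq=random_dna(cfg.genome_len, rng), taxon="donor"
    )
    te, te_annotations = make_te(cfg.te_len, cfg.ltr_len, cfg.seed)

    donor_pos = int(rng.integers(cfg.te_len, cfg.genome_len - cfg.te_len))
    donor_genome, donor_te = insert_te(background, te, donor_pos, cfg.tsd_len)

    recipient_bg = mutate(background, cfg.vertical_divergence, cfg.seed,
                          indel_rate=cfg.indel_rate)
    recipient_bg = SeqRecord(id="recipient_genome", seq=recipient_bg.seq,
                             taxon="recipient")

    n_copies = 1 + cfg.n_amplified_copies
    copies = [mutate(te, cfg.ht_divergence, cfg.seed)]
    for i in range(cfg.n_amplified_copies):
        copies.append(mutate(copies[0], cfg.amplified_divergence, cfg.seed + 1000 + i))

    positions = _pick_positions(
        rng, cfg.genome_len, n_copies, min_gap=cfg.te_len + 2000,
        margin=cfg.tsd_len + 1000,
    )
    # Insert right-to-left so earlier coordinates stay valid; truth intervals
    # account for the cumulative shift from copies inserted to the left.
    genome = recipient_bg
    for p, copy in zip(reversed(positions), reversed(copies)):
        copy = SeqRecord(id="ht_te", seq=copy.seq)
        genome, _ = insert_te(genome, copy, p, cfg.tsd_len)
    truth = []
    shift = 0
    for i, p in enumerate(positions):
        start = p + shift + cfg.tsd_len
        truth.append(
            Interval(genome.id, start, start + cfg.te_len - 1, "TE", f"ht_copy_{i}")
        )
        shift += cfg.te_len + cfg.tsd_len

    donor_reads = shred(donor_genome, cfg.read_len, cfg.coverage, cfg.seed,
                        read_len_min=cfg.read_len_min,
                        trimmed_fraction=cfg.trimmed_fraction)

    cds = _sample_cds_windows(rng, genome, truth, cfg.n_cds, cfg.cds_len)
    return HTScenario(
        config=cfg,
        donor_genome=donor_genome,
        recipient_genome=genome,
        donor_reads=donor_reads,
        truth=truth,
        te=te,
        te_annotations=te_annotations,
        donor_te_interval=donor_te,
        cds=cds,
    )


def build_vertical_scenario(
    config: SimConfig, shared_te: bool = True
) -> HTScenario:
    """A no-transfer control: the same element, inherited vertically.

    With ``shared_te`` the ancestor already carries the element, so both
    genomes inherit it and the copies diverge with the background to
    ``vertical_divergence`` — homologous, but only at speciation-level
    identity.  Without it the element arose in the donor after the split
    and the recipient carries nothing.  ``truth`` is empty either way:
    any HT call on this scenario is a false positive.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 401])
    background = SeqRecord(
        id="donor_genome", seq=random_dna(cfg.genome_len, rng), taxon="donor"
    )
    te, te_annotations = make_te(cfg.te_len, cfg.ltr_len, cfg.seed)
    donor_pos = int(rng.integers(cfg.te_len, cfg.genome_len - cfg.te_len))
    donor_genome, donor_te = insert_te(background, te, donor_pos, cfg.tsd_len)

    ancestor = donor_genome if shared_te else background
    recipient = mutate(ancestor, cfg.vertical_divergence, cfg.seed,
                       indel_rate=cfg.indel_rate)
    recipient = SeqRecord(id="recipient_genome", seq=recipient.seq,
                          taxon="recipient")
    donor_reads = shred(donor_genome, cfg.read_len, cfg.coverage, cfg.seed,
                        read_len_min=cfg.read_len_min,
                        trimmed_fraction=cfg.trimmed_fraction)
    exclude = []
    if shared_te:
        exclude = [Interval(recipient.id, donor_te.start, donor_te.end, "TE",
                            "vertical_te")]
    cds = _sample_cds_windows(rng, recipient, exclude, cfg.n_cds, cfg.cds_len)
    return HTScenario(
        config=cfg,
        donor_genome=donor_genome,
        recipient_genome=recipient,
        donor_reads=donor_reads,
        truth=[],
        te=te,
        te_annotations=te_annotations,
        donor_te_interval=donor_te,
        cds=cds,
    )


def _sample_cds_windows(
    rng: np.random.Generator,
    genome: SeqRecord,
    exclude: Sequence[Interval],
    n: int,
    length: int,
) -> list[SeqRecord]:
    """Pseudo-CDS windows from the recipient background, clear of planted TEs."""
    margin = 200
    blocked = sorted((iv.start - margin, iv.end + margin) for iv in exclude)
    windows: list[SeqRecord] = []
    tries = 0
    while len(windows) < n and tries < 10_000:
        tries += 1
        s = int(rng.integers(1, len(genome) - length))
        e = s + length - 1
        if any(bs <= e and s <= be for bs, be in blocked):
            continue
        if any(abs(s - int(w.description)) < length for w in windows):
            continue
        windows.append(
            SeqRecord(id=f"cds_{len(windows):04d}", seq=genome.seq[s - 1: e],
                      taxon=genome.taxon, description=str(s))
        )
    if len(windows) < n:
        raise RuntimeError("could not sample enough CDS windows")
    return windows
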