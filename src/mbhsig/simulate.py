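"""Synthetic data generation with recorded ground truth.

Generates every input the pipeline consumes — signature-planted protein
families, metagenome-style fragments, hit tables, CDS tables and
group-conditional metadata — so every stage is testable without downloads.

The generator emulates the structure of the study system: a mined database of
full-length group 1 NiFe MBH small subunits split into a 6C (O2-tolerant) and
a 4C (standard) family, plus metagenome-derived fragments of those proteins
ranging from full length down to 35 residues, with per-organism taxon, oxygen
class and environment-term metadata whose group-conditional proportions are
controllable (the defaults plant the headline contrasts between the groups:
aerobes heavily enriched in the 6C group, anaerobes in the 4C group, and
phyla that occur in only one group).

One global integer seed fans out to per-stage substreams derived by stable
hashing of stage names, so adding a stage never perturbs earlier stages.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqio import (
    AnnotationRecord,
    CDSRecord,
    HitRecord,
    ProteinRecord,
    write_annotations,
    write_cds,
    write_fasta,
    write_hits,
)
from .signature import SignatureScheme, save_scheme

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_POSITIONS = (17, 62, 120, 163, 219, 268)
DEFAULT_DISCRIMINATING = (62, 163)

#: Group-conditional metadata distributions. Taxon and oxygen entries are
#: probability vectors; environment entries are mean term frequencies
#: (per-sequence counts are Poisson around them). The oxygen proportions
#: plant a ~28.5-fold aerobe excess in the 6C group and a ~2.54-fold
#: anaerobe excess in the 4C group; the taxon proportions plant one-group
#: exclusives (CFB/GSB only 6C; Euryarchaeota/GNS/epsilon only 4C) and
#: fold contrasts near 8, 17.8 and 16.8 for delta/alpha/beta proteobacteria.
DEFAULT_METADATA: dict[str, dict[str, dict[str, float]]] = {
    "6C": {
        "taxon_group": {
            "delta-proteobacteria": 0.02,
            "alpha-proteobacteria": 0.1777,
            "beta-proteobacteria": 0.1684,
            "CFB": 0.06,
            "GSB": 0.04,
            "other": 0.5339,
        },
        "oxygen_class": {"aerobe": 0.57, "anaerobe": 0.26, "versatile": 0.17},
        "env_terms": {
            "freshwater": 2.0,
            "terrestrial": 1.5,
            "lake_sediment": 1.0,
            "marine": 0.25,
            "geothermal": 0.25,
        },
    },
    "4C": {
        "taxon_group": {
            "delta-proteobacteria": 0.1604,
            "alpha-proteobacteria": 0.01,
            "beta-proteobacteria": 0.01,
            "Euryarchaeota": 0.10,
            "GNS": 0.05,
            "epsilon-proteobacteria": 0.05,
            "other": 0.6196,
        },
        "oxygen_class": {"aerobe": 0.02, "anaerobe": 0.66, "versatile": 0.32},
        "env_terms": {
            "marine": 2.0,
            "saline": 1.25,
            "geothermal": 1.0,
            "freshwater": 0.5,
            "terrestrial": 0.25,
        },
    },
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage RNG derived from the global seed by hashing the stage name."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults mirror the study system scale: a database of 63 O2-tolerant (6C)
    and 114 standard (4C) full-length small subunits of ~350 residues, of
    which a fifth are emitted as metagenome-style fragments between 35
    residues and full length, diverged from their family reference at 10%
    substitutions with the signature positions conserved.
    """

    seed: int = 0
    n_6C: int = 63
    n_4C: int = 114
    ref_length: int = 350
    large_ref_length: int = 350
    sub_rate: float = 0.10
    indel_rate: float = 0.0
    indel_mean_len: float = 3.0
    fragment_fraction: float = 0.2
    fragment_len_range: tuple[int, int] = (35, 350)
    protect_signature: bool = True
    coverage_noise_sd: float = 0.0
    n_decoy_cds: int = 5
    positions: tuple[int, ...] = DEFAULT_POSITIONS
    discriminating: tuple[int, int] = DEFAULT_DISCRIMINATING
    metadata_distributions: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: DEFAULT_METADATA
    )

    def __post_init__(self) -> None:
        for name in ("sub_rate", "indel_rate", "fragment_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.fragment_len_range
        if not 1 <= lo <= hi <= self.ref_length:
            raise ValueError(
                f"fragment_len_range {self.fragment_len_range} outside [1, {self.ref_length}]"
            )
        if max(self.positions) >= self.ref_length:
            raise ValueError("signature positions must fit inside ref_length")
        for group, dists in self.metadata_distributions.items():
            for axis in ("taxon_group", "oxygen_class"):
                probs = dists[axis]
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
                    raise ValueError(
                        f"{group}/{axis} is not a probability vector (sums to {total})"
                    )
            if any(m < 0 for m in dists["env_terms"].values()):
                raise ValueError(f"{group}/env_terms has a negative mean")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted sequence."""

    seq_id: str
    true_group: str
    parent_id: str
    n_substitutions: int
    has_indels: bool
    fragment_span: tuple[int, int] | None  # 1-based inclusive, parent coordinates
    positions_covered: tuple[int, ...] | None  # scheme positions inside the span


@dataclass(frozen=True)
class GroundTruth:
    """Per-sequence truth records plus the planted metadata distributions."""

    records: Mapping[str, TruthRecord]
    metadata_distributions: Mapping[str, Mapping[str, Mapping[str, float]]]

    def __getitem__(self, seq_id: str) -> TruthRecord:
        return self.records[seq_id]


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length)]


def make_references(
    config: SimulationConfig,
) -> tuple[ProteinRecord, ProteinRecord, ProteinRecord, SignatureScheme]:
    """Build the 6C and 4C small-subunit references, the large-subunit
    reference, and the signature scheme in the 6C reference's frame.

    The 6C reference carries Cys at all six signature positions; the 4C
    reference carries Gly at the two discriminating positions and Cys at the
    other four; the large reference carries His at the supporting position.
    Reproducible from the config seed.
    """
    rng = stage_rng(config.seed, "references")
    base = _random_sequence(rng, config.ref_length)
    seq6 = list(base)
    for p in config.positions:
        seq6[p - 1] = "C"
    seq4 = list(seq6)
    for p in config.discriminating:
        seq4[p - 1] = "G"
    large = _random_sequence(rng, config.large_ref_length)
    large_pos = min(229, config.large_ref_length)
    large[large_pos - 1] = "H"

    ref6 = ProteinRecord(id="ref_6C", sequence="".join(seq6),
                         description="synthetic 6C small-subunit reference")
    ref4 = ProteinRecord(id="ref_4C", sequence="".join(seq4),
                         description="synthetic 4C small-subunit reference")
    ref_large = ProteinRecord(id="ref_large", sequence="".join(large),
                              description="synthetic large-subunit reference")
    scheme = SignatureScheme(
        reference=ref6,
        positions=config.positions,
        discriminating=config.discriminating,
        large_reference=ref_large,
        large_position=large_pos,
    )
    return ref6, ref4, ref_large, scheme


def evolve_family(
    ref: ProteinRecord,
    n: int,
    sub_rate: float,
    indel_rate: float,
    protect: Sequence[int],
    seed: int,
    indel_mean_len: float = 3.0,
    id_prefix: str = "seq",
    true_group: str = "unknown",
    stage: str = "family",
) -> tuple[list[ProteinRecord], dict[str, TruthRecord]]:
    """Evolve ``n`` descendants of ``ref`` as a star family.

    Substitutions are i.i.d. per residue (uniform over the 19 alternatives);
    indels initiate per residue with geometric lengths. Protected (1-based)
    positions are never substituted and never deleted.
    """
    protect_idx = {p - 1 for p in protect}
    if protect_idx and max(protect_idx) >= len(ref):
        raise ValueError("protected position beyond reference length")
    rng = stage_rng(seed, stage)
    records: list[ProteinRecord] = []
    truth: dict[str, TruthRecord] = {}
    for i in range(n):
        seq = list(ref.sequence)
        n_subs = 0
        hit = rng.random(len(seq)) < sub_rate
        for idx in np.flatnonzero(hit):
            if idx in protect_idx:
                continue
            current = seq[idx]
            alternatives = [a for a in AMINO_ACIDS if a != current]
            seq[idx] = alternatives[rng.integers(0, len(alternatives))]
            n_subs += 1
        has_indels = False
        if indel_rate > 0:
            starts = np.flatnonzero(rng.random(len(seq)) < indel_rate)
            # apply right-to-left so earlier indices stay valid
            for idx in starts[::-1]:
                length = int(rng.geometric(1.0 / indel_mean_len))
                if rng.random() < 0.5:
                    span = set(range(idx, min(idx + length, len(seq))))
                    if span & protect_idx:
                        continue
                    del seq[idx: idx + length]
                else:
                    seq[idx:idx] = _random_sequence(rng, length)
                has_indels = True
        sid = f"{id_prefix}_{i:04d}"
        records.append(
            ProteinRecord(id=sid, sequence="".join(seq),
                          description=f"descendant of {ref.id}")
        )
        truth[sid] = TruthRecord(
            seq_id=sid, true_group=true_group, parent_id=ref.id,
            n_substitutions=n_subs, has_indels=has_indels,
            fragment_span=None, positions_covered=None,
        )
    return records, truth


def fragmentize(
    records: Sequence[ProteinRecord],
    truth: Mapping[str, TruthRecord],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[ProteinRecord], dict[str, TruthRecord]]:
    """Replace a random fraction of sequences by uniformly positioned
    substrings with lengths uniform in ``fragment_len_range``.

    Fragments keep their id and are tagged ``source="metagenome"``. Truth
    records gain the span (1-based, parent coordinates) and, for indel-free
    parents (parent coordinates == reference coordinates), the scheme
    positions the span covers.
    """
    rng = stage_rng(seed if seed is not None else config.seed, "fragmentize")
    lo, hi = config.fragment_len_range
    out_records: list[ProteinRecord] = []
    out_truth: dict[str, TruthRecord] = {}
    for rec in records:
        t = truth[rec.id]
        if rng.random() >= config.fragment_fraction:
            out_records.append(rec)
            out_truth[rec.id] = t
            continue
        max_len = min(hi, len(rec))
        min_len = min(lo, max_len)
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(1, len(rec) - length + 2))  # 1-based
        end = start + length - 1
        covered = None
        if not t.has_indels:
            covered = tuple(p for p in config.positions if start <= p <= end)
        out_records.append(
            ProteinRecord(
                id=rec.id,
                sequence=rec.sequence[start - 1: end],
                description=f"fragment {start}-{end} of {t.parent_id}",
                source="metagenome",
            )
        )
        out_truth[rec.id] = replace(t, fragment_span=(start, end), positions_covered=covered)
    return out_records, out_truth


def span_miss_probability(
    parent_length: int,
    len_range: tuple[int, int],
    positions: Sequence[int],
) -> float:
    """Closed-form probability that a random fragment covers none of
    ``positions``.

    Matches the fragmentize sampling scheme exactly: length L uniform on
    ``len_range`` (clipped to the parent), start uniform on the valid starts
    for that length. Computed by summing, for each L, the fraction of starts
    whose span [s, s+L-1] avoids every position (interval union over the
    per-position covering-start windows).
    """
    lo, hi = len_range
    hi = min(hi, parent_length)
    lo = min(lo, hi)
    total = 0.0
    n_lengths = hi - lo + 1
    for L in range(lo, hi + 1):
        n_starts = parent_length - L + 1
        windows = sorted(
            (max(1, p - L + 1), min(p, n_starts)) for p in positions
        )
        covered = 0
        cur_lo, cur_hi = None, None
        for a, b in windows:
            if b < a:
                continue
            if cur_lo is None:
                cur_lo, cur_hi = a, b
            elif a <= cur_hi + 1:
                cur_hi = max(cur_hi, b)
            else:
                covered += cur_hi - cur_lo + 1
                cur_lo, cur_hi = a, b
        if cur_lo is not None:
            covered += cur_hi - cur_lo + 1
        total += (n_starts - covered) / n_starts
    return total / n_lengths


def _draw_categorical(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    cats = sorted(dist)
    probs = np.array([dist[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    return cats[rng.choice(len(cats), p=probs)]


def make_metadata(
    truth: GroundTruth | Mapping[str, TruthRecord],
    config: SimulationConfig,
    seed: int | None = None,
) -> list[AnnotationRecord]:
    """Draw group-conditional metadata for every sequence in the truth set.

    Taxon group and oxygen class are categorical draws from the sequence's
    true group's distributions; environment-term frequencies are Poisson
    around the configured per-term means.
    """
    records = truth.records if isinstance(truth, GroundTruth) else truth
    rng = stage_rng(seed if seed is not None else config.seed, "metadata")
    out: list[AnnotationRecord] = []
    for sid in sorted(records):
        t = records[sid]
        dists = config.metadata_distributions[t.true_group]
        taxon = _draw_categorical(rng, dists["taxon_group"])
        oxygen = _draw_categorical(rng, dists["oxygen_class"])
        env: dict[str, int] = {}
        for term in sorted(dists["env_terms"]):
            freq = int(rng.poisson(dists["env_terms"][term]))
            if freq > 0:
                env[term] = freq
        out.append(
            AnnotationRecord(
                seq_id=sid,
                organism=f"synthetic organism {sid}",
                group=t.true_group,
                taxon_group=taxon,
                oxygen_class=oxygen,
                env_terms=env,
            )
        )
    return out


def make_hit_and_cds_tables(
    records: Sequence[ProteinRecord],
    truth: Mapping[str, TruthRecord],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[HitRecord], list[CDSRecord]]:
    """Build the hit table and the CDS/EC annotation table for a record set.

    Hit coverage is the true fraction of the generating reference covered by
    the sequence's span (plus optional Gaussian noise), so fragments fall
    below the 80% mining filter in an analytically predictable way. CDS
    records carry EC 1.12.-.- for true hydrogenases; ``n_decoy_cds`` decoy
    records with non-hydrogenase EC numbers are appended.
    """
    rng = stage_rng(seed if seed is not None else config.seed, "tables")
    hits: list[HitRecord] = []
    cds: list[CDSRecord] = []
    for rec in records:
        t = truth[rec.id]
        if t.fragment_span is None:
            coverage = 100.0
        else:
            s, e = t.fragment_span
            coverage = 100.0 * (e - s + 1) / config.ref_length
        if config.coverage_noise_sd > 0:
            coverage += rng.normal(0.0, config.coverage_noise_sd)
        coverage = float(min(100.0, max(0.0, coverage)))
        identity = 100.0 * (1.0 - t.n_substitutions / max(1, len(rec)))
        identity = float(min(100.0, max(0.0, identity)))
        hits.append(HitRecord(query_id=rec.id, subject_id=t.parent_id,
                              query_coverage=coverage, identity=identity))
        cds.append(
            CDSRecord(
                contig_id=f"ctg_{rec.id}",
                cds_id=rec.id,
                start=1,
                end=3 * len(rec),
                strand="+",
                product="NiFe hydrogenase small subunit",
                ec_numbers=("1.12.-.-",),
                translation=rec.sequence,
            )
        )
    decoy_ecs = ("1.1.1.1", "3.2.1.4", "2.7.7.7")
    for i in range(config.n_decoy_cds):
        ec = decoy_ecs[i % len(decoy_ecs)]
        cds.append(
            CDSRecord(
                contig_id=f"ctg_decoy_{i:03d}",
                cds_id=f"decoy_{i:03d}",
                start=1,
                end=300,
                strand="-",
                product="decoy enzyme",
                ec_numbers=(ec,),
                translation=None,
            )
        )
    return hits, cds


@dataclass(frozen=True)
class DatasetBundle:
    """A complete synthetic dataset: sequences, tables, truth and scheme."""

    config: SimulationConfig
    scheme: SignatureScheme
    ref_4C: ProteinRecord
    database: list[ProteinRecord]
    metagenome: list[ProteinRecord]
    truth: GroundTruth
    annotations: list[AnnotationRecord]
    hits: list[HitRecord]
    cds: list[CDSRecord]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.database, out / "database.fasta")
        write_fasta(self.metagenome, out / "metagenome.fasta")
        write_annotations(self.annotations, out / "annotations.tsv")
        write_hits(self.hits, out / "hits.tsv")
        write_cds(self.cds, out / "cds.tsv")
        save_scheme(self.scheme, out / "scheme.cfg")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("seq_id\ttrue_group\tparent_id\tn_substitutions\thas_indels"
                     "\tfragment_start\tfragment_end\tpositions_covered\n")
            for sid in sorted(self.truth.records):
                t = self.truth.records[sid]
                span = t.fragment_span or ("", "")
                pc = (";".join(map(str, t.positions_covered))
                      if t.positions_covered is not None else "")
                fh.write(f"{sid}\t{t.true_group}\t{t.parent_id}\t{t.n_substitutions}"
                         f"\t{int(t.has_indels)}\t{span[0]}\t{span[1]}\t{pc}\n")


def make_dataset(config: SimulationConfig) -> DatasetBundle:
    """Generate the full synthetic study: classified database families plus
    metagenome-style fragments, with metadata, hit and CDS tables.

    ``n_6C + n_4C`` descendants are evolved from the planted references;
    ``fragment_fraction`` of them are emitted as fragments (the metagenome
    set), the rest full-length (the database set). Metadata covers the
    database set, hit/CDS tables cover everything.
    """
    ref6, ref4, _, scheme = make_references(config)
    protect = config.positions if config.protect_signature else ()
    fam6, truth6 = evolve_family(
        ref6, config.n_6C, config.sub_rate, config.indel_rate, protect,
        config.seed, config.indel_mean_len, id_prefix="t6c",
        true_group="6C", stage="family_6C",
    )
    fam4, truth4 = evolve_family(
        ref4, config.n_4C, config.sub_rate, config.indel_rate, protect,
        config.seed, config.indel_mean_len, id_prefix="s4c",
        true_group="4C", stage="family_4C",
    )
    records = fam6 + fam4
    truth_map = {**truth6, **truth4}
    records, truth_map = fragmentize(records, truth_map, config)
    database = [r for r in records if r.source == "database"]
    metagenome = [r for r in records if r.source == "metagenome"]
    truth = GroundTruth(records=truth_map,
                        metadata_distributions=config.metadata_distributions)
    db_truth = {r.id: truth_map[r.id] for r in database}
    annotations = make_metadata(db_truth, config)
    hits, cds = make_hit_and_cds_tables(records, truth_map, config)
    return DatasetBundle(
        config=config, scheme=scheme, ref_4C=ref4, database=database,
        metagenome=metagenome, truth=truth, annotations=annotations,
        hits=hits, cds=cds,
    )
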