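"""Synthetic genomes, features, families and mock coarse tracks.

Every downstream stage of the pipeline has a recovery test against data
generated here, with the ground truth recorded in a manifest:

* random background sequence at a controllable GC content;
* pseudogene-like stranded features with a nucleosome-inhibitory element
  (a poly-dA:dT run, which is genuinely stiff under the dinucleotide
  parameters and therefore energetically disfavoured, not merely painted)
  written immediately upstream of each start anchor and downstream of each
  end anchor, strand-respecting;
* families of degenerate copies of parent sequences, mutated at graded
  per-member rates with an A/T bias so that identity and GC co-decay, the
  way pseudogene sequences drift after losing function;
* coarse (10-bp-bin) noisy "experimental" occupancy tracks with smooth
  depletion dips at the ground-truth element positions, painted
  independently of sequence to mimic in vivo occupancy that reflects more
  than sequence.

All generators are deterministic under ``SimConfig.seed``; each draws from
its own seeded stream, so outputs do not depend on call order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .profiles import Feature, FeatureSet
from .tracks import CoarseTrack

__all__ = [
    "DepletionElement",
    "FamilySpec",
    "TrackNoise",
    "SimConfig",
    "simulate_genome",
    "simulate_features_with_depletion",
    "simulate_family_cohort",
    "simulate_coarse_track",
    "write_simulation",
    "gc_fraction",
]

_BASES = np.array(list("ACGT"))


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class DepletionElement:
    """Nucleosome-inhibitory sequence element flanking feature anchors."""

    length: int = 150           # bp
    composition: str = "A"      # repeated unit; poly-dA:dT by default

    def sequence(self) -> str:
        reps = -(-self.length // len(self.composition))
        return (self.composition * reps)[: self.length]


@dataclass(frozen=True)
class FamilySpec:
    """Parent genes spawning degenerate copies at graded mutation rates."""

    n_families: int = 50
    members_per_family: int = 20
    member_length: int = 500            # bp
    max_mutation_rate: float = 0.4      # per-site substitution probability
    at_bias: float = 0.9                # probability a substitution lands on A or T

    def __post_init__(self) -> None:
        if not 0 <= self.max_mutation_rate <= 1:
            raise ValueError("max_mutation_rate must lie in [0, 1]")
        if not 0 <= self.at_bias <= 1:
            raise ValueError("at_bias must lie in [0, 1]")


@dataclass(frozen=True)
class TrackNoise:
    """Shape of the mock coarse experimental track."""

    bin_size: int = 10
    baseline: float = 1.0
    noise_sd: float = 0.1
    dip_depth: float = 0.5
    dip_sd: float = 50.0    # Gaussian dip scale (bp); dip centred on each element


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 1
    chromosome_length: int = 250_000
    background_gc: float = 0.5
    n_features_per_group: int = 25          # per transcription_status group
    feature_length_range: tuple[int, int] = (500, 1500)
    feature_margin: int = 1500              # clear bp between/around features
    element: DepletionElement = field(default_factory=DepletionElement)
    family: FamilySpec = field(default_factory=FamilySpec)
    track: TrackNoise = field(default_factory=TrackNoise)

    def __post_init__(self) -> None:
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must lie in (0, 1)")
        if self.feature_length_range[0] < 129:
            raise ValueError("minimum feature length must be >= 129 bp")
        if self.feature_margin <= self.element.length:
            raise ValueError("feature_margin must exceed the element length")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def simulate_genome(cfg: SimConfig) -> dict[str, str]:
    """i.i.d. background chromosomes at ``background_gc``; seed-deterministic."""
    rng = cfg.rng(1)
    return {
        f"chr{i + 1}": _random_sequence(rng, cfg.chromosome_length, cfg.background_gc)
        for i in range(cfg.n_chromosomes)
    }


def simulate_features_with_depletion(
    cfg: SimConfig, sequences: dict[str, str]
) -> tuple[FeatureSet, dict[str, str], dict]:
    """Lay out stranded features and write inhibitory elements at anchors.

    Features (half transcribed, half nontranscribed, per
    ``n_features_per_group``) are packed left to right with
    ``feature_margin`` clear bp between them.  For every feature one
    element is written immediately upstream of the biological start and
    one immediately downstream of the biological end (for minus-strand
    features those are the genomically higher and lower sides
    respectively).  Returns the features, the edited sequences and a
    ground-truth manifest of element coordinates.

    Raises when the requested features do not fit.
    """
    rng = cfg.rng(2)
    groups = ["transcribed"] * cfg.n_features_per_group + [
        "nontranscribed"
    ] * cfg.n_features_per_group
    rng.shuffle(groups)
    lo, hi = cfg.feature_length_range
    lengths = rng.integers(lo, hi + 1, size=len(groups))
    strands = rng.choice(["+", "-"], size=len(groups))
    biotypes = rng.choice(["processed", "duplicated"], size=len(groups))

    edited = {k: list(v) for k, v in sequences.items()}
    chrom_ids = sorted(sequences)
    features = []
    manifest_features = []
    chrom_iter = iter(chrom_ids)
    chrom = next(chrom_iter)
    cursor = cfg.feature_margin
    elem_seq = cfg.element.sequence()
    elen = cfg.element.length

    for k, (group, length, strand, biotype) in enumerate(
        zip(groups, lengths, strands, biotypes)
    ):
        while cursor + length + cfg.feature_margin > len(sequences[chrom]):
            try:
                chrom = next(chrom_iter)
            except StopIteration:
                raise ValueError(
                    "features do not fit: increase chromosome_length or "
                    "n_chromosomes, or reduce n_features_per_group"
                ) from None
            cursor = cfg.feature_margin
        start, end = cursor, cursor + int(length)
        fid = f"pg{k + 1:04d}"
        feat = Feature(
            seq_id=chrom,
            start=start,
            end=end,
            feature_id=fid,
            strand=str(strand),
            transcription_status=group,
            biotype=str(biotype),
        )
        features.append(feat)
        # biological upstream-of-start / downstream-of-end element intervals
        if strand == "+":
            up = (start - elen, start)
            down = (end, end + elen)
        else:
            up = (end, end + elen)
            down = (start - elen, start)
        for a, b in (up, down):
            edited[chrom][a:b] = list(elem_seq)
        manifest_features.append(
            {
                "feature_id": fid,
                "seq_id": chrom,
                "start": start,
                "end": end,
                "strand": str(strand),
                "transcription_status": group,
                "element_upstream_of_start": list(up),
                "element_downstream_of_end": list(down),
            }
        )
        cursor = end + cfg.feature_margin

    manifest = {
        "kind": "features_with_depletion",
        "element": asdict(cfg.element),
        "element_offset_range": [-elen, 0],
        "features": manifest_features,
    }
    return FeatureSet(features), {k: "".join(v) for k, v in edited.items()}, manifest


def simulate_family_cohort(
    cfg: SimConfig, null_attributes: bool = False
) -> tuple[FeatureSet, dict[str, str], dict]:
    """Families of degenerate copies with exact identity/GC bookkeeping.

    Each family has one parent sequence at ``background_gc``; member ``j``
    of ``m`` is mutated at per-site rate ``max_mutation_rate * j/(m-1)``
    (graded from an exact copy to the maximum), substitutions landing on
    A/T with probability ``at_bias``.  Each member is emitted as its own
    sequence with a feature spanning it; recorded identity is the exact
    fraction of positions matching the parent, recorded GC the exact
    member GC, and divergence the applied per-site rate.

    With ``null_attributes`` the gc/identity/divergence columns are
    replaced by independent random draws, breaking any association with
    the sequences — the null cohort for significance calibration.
    """
    fam = cfg.family
    rng = cfg.rng(3)
    sequences: dict[str, str] = {}
    features = []
    manifest_members = []
    for f in range(fam.n_families):
        family_id = f"fam{f + 1:03d}"
        parent = _random_sequence(rng, fam.member_length, cfg.background_gc)
        parent_arr = np.array(list(parent))
        for j in range(fam.members_per_family):
            denom = max(fam.members_per_family - 1, 1)
            rate = fam.max_mutation_rate * j / denom
            member = parent_arr.copy()
            hit = rng.random(fam.member_length) < rate
            for pos in np.flatnonzero(hit):
                member[pos] = _mutate_base(rng, member[pos], fam.at_bias)
            seq = "".join(member)
            identity = float((member == parent_arr).mean())
            sid = f"{family_id}_m{j + 1:02d}"
            sequences[sid] = seq
            features.append(
                Feature(
                    seq_id=sid,
                    start=0,
                    end=fam.member_length,
                    feature_id=sid,
                    strand="+",
                    biotype="processed",
                    gc_content=gc_fraction(seq),
                    identity=identity,
                    divergence=rate,
                    family_id=family_id,
                )
            )
            manifest_members.append(
                {
                    "feature_id": sid,
                    "family_id": family_id,
                    "mutation_rate": rate,
                    "identity": identity,
                    "gc_content": gc_fraction(seq),
                }
            )
    if null_attributes:
        null_rng = cfg.rng(4)
        shuffled = []
        for feat in features:
            shuffled.append(
                Feature(
                    seq_id=feat.seq_id,
                    start=feat.start,
                    end=feat.end,
                    feature_id=feat.feature_id,
                    strand=feat.strand,
                    biotype=feat.biotype,
                    gc_content=float(null_rng.uniform(0.3, 0.7)),
                    identity=float(null_rng.uniform(0.6, 1.0)),
                    divergence=float(null_rng.uniform(0.0, 0.5)),
                    family_id=feat.family_id,
                )
            )
        features = shuffled
    manifest = {
        "kind": "family_cohort",
        "family_spec": asdict(fam),
        "null_attributes": null_attributes,
        "members": manifest_members,
    }
    return FeatureSet(features), sequences, manifest


def _mutate_base(rng: np.random.Generator, base: str, at_bias: float) -> str:
    w = np.array([at_bias / 2, (1 - at_bias) / 2, (1 - at_bias) / 2, at_bias / 2])
    w[np.flatnonzero(_BASES == base)] = 0.0
    w = w / w.sum()
    return str(_BASES[rng.choice(4, p=w)])


def simulate_coarse_track(
    cfg: SimConfig,
    sequences: dict[str, str],
    features: FeatureSet,
) -> dict[str, CoarseTrack]:
    """Mock experimental occupancy at coarse resolution, dips at anchors.

    Per chromosome: bins of ``bin_size`` bp with value baseline + Gaussian
    noise, minus a Gaussian-shaped dip of ``dip_depth`` (scale ``dip_sd``)
    centred on each ground-truth inhibitory-element midpoint.  The dips
    are painted independently of the underlying sequence.  Values are
    floored just above zero (occupancy is positive).
    """
    tn = cfg.track
    rng = cfg.rng(5)
    elen = cfg.element.length
    centres: dict[str, list[float]] = {sid: [] for sid in sequences}
    for feat in features:
        if feat.seq_id not in centres:
            continue
        if feat.strand == "+":
            centres[feat.seq_id] += [feat.start - elen / 2, feat.end + elen / 2]
        else:
            centres[feat.seq_id] += [feat.end + elen / 2, feat.start - elen / 2]
    out = {}
    for sid in sorted(sequences):
        L = len(sequences[sid])
        starts = np.arange(0, L - tn.bin_size + 1, tn.bin_size)
        mids = starts + tn.bin_size / 2
        vals = tn.baseline + rng.normal(0.0, tn.noise_sd, size=len(starts))
        for c in centres[sid]:
            vals -= tn.dip_depth * np.exp(-0.5 * ((mids - c) / tn.dip_sd) ** 2)
        vals = np.maximum(vals, 1e-3)
        out[sid] = CoarseTrack(sid, starts, starts + tn.bin_size, vals)
    return out


def write_simulation(cfg: SimConfig, outdir: str | Path) -> dict:
    """Run the full generator suite and write all artefacts to ``outdir``.

    Emits genome.fasta, features.bed, features.tsv, experimental.bedGraph
    (coarse), manifest.json; returns the manifest.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(cfg)
    features, edited, manifest = simulate_features_with_depletion(cfg, genome)
    coarse = simulate_coarse_track(cfg, edited, features)

    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sorted(edited.items())]
    SeqIO.write(records, outdir / "genome.fasta", "fasta")
    features.write_bed(outdir / "features.bed", outdir / "features.tsv")
    with open(outdir / "experimental.bedGraph", "w") as fh:
        for sid in sorted(coarse):
            tr = coarse[sid]
            for s, e, v in zip(tr.starts, tr.ends, tr.values):
                fh.write(f"{sid}\t{s}\t{e}\t{v:.6g}\n")
    manifest = dict(manifest)
    manifest["config"] = asdict(cfg)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
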