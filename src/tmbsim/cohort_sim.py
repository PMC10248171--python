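"""Synthetic somatic-variant cohorts with per-site sequencing evidence.

Truth variant sets are planted on an abstract single contig ("chrS") and each
site carries the evidence vector a short-read caller would inspect: local
depth relative to the expected depth, the standardized insert-size shift of
spanning read pairs, the fraction of split reads, the fraction of mismatching
bases, and read-orientation evidence.  Five mutation classes are modelled —
SNV, insertion (INS), deletion (DEL), inversion (INV) and tandem duplication
(DUP) — each leaving a distinct signature:

    DEL  depth drops, insert size stretches, split reads appear
    INS  insert size shrinks, split reads appear
    INV  read-orientation evidence, split reads appear
    DUP  depth rises, split reads appear
    SNV  mismatch fraction near the variant allele fraction, depth unchanged

In the zero-noise limit these signatures are disjoint, so a rule set matched
to them recovers the truth exactly; dialing noise up makes the supports
overlap and detection errors appear.  No nucleotide sequence or reads are
generated — the study operates entirely at the feature level, so sample sizes
that would need a read simulator and a reference genome reduce to a few
thousand feature vectors.

Split-read and orientation evidence are treated as breakpoint-specific: sites
without a structural breakpoint (SNVs and background positions) carry a split
fraction of zero and orientation noise only.  Read-level split artifacts are
not modelled.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "VTYPES",
    "ValidationError",
    "CapacityError",
    "SeqNoise",
    "VariantRecord",
    "SiteFeatures",
    "SampleSpec",
    "SyntheticSample",
    "plant_variants",
    "simulate_site_features",
    "simulate_background_sites",
    "synthesize_sample",
    "make_cohort",
    "feature_location",
    "fraction_beta_params",
    "fraction_noise_sd",
    "write_truth_vcf",
    "write_truth_csv",
    "write_cohort_manifest",
]

#: Canonical mutation-type order used for composition vectors.
VTYPES: tuple[str, ...] = ("SNV", "INS", "DEL", "INV", "DUP")


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class CapacityError(ValidationError):
    """The region cannot host the requested number of distinct sites."""


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeqNoise:
    """Parameters of the feature generative model.

    ``scale`` multiplies every dispersion parameter; ``scale = 0`` is the
    noise-free limit in which each feature collapses onto its type-conditional
    location.  Remaining fields are the dispersions at ``scale = 1``:

    - ``depth_sigma``: log-scale SD of the depth ratio (lognormal around the
      type median).
    - ``insert_sigma``: SD of the standardized insert-size shift (normal).
    - ``frac_sd``: SD of split/mismatch fractions (beta, matched mean and SD).
    - ``orient_error``: probability of spurious orientation evidence at a
      non-inverted site.
    - ``inv_miss``: probability of missing orientation evidence at an
      inversion.
    - ``background_mismatch`` / ``background_split``: mean mismatch and split
      fractions at sites without a variant (both scale with ``scale`` so the
      noise-free background is exactly clean).
    """

    scale: float = 1.0
    depth_sigma: float = 0.08
    insert_sigma: float = 0.5
    frac_sd: float = 0.04
    orient_error: float = 0.01
    inv_miss: float = 0.05
    background_mismatch: float = 0.01
    background_split: float = 0.0

    def validate(self) -> None:
        if self.scale < 0:
            raise ValidationError("seq_noise.scale must be >= 0")
        for name in ("depth_sigma", "insert_sigma", "frac_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"seq_noise.{name} must be >= 0")
        for name in ("orient_error", "inv_miss", "background_mismatch",
                     "background_split"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"seq_noise.{name} must be in [0, 1]")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One planted (or called) variant on the synthetic contig."""

    site_id: int
    position: int          # 1-based
    vtype: str
    length: int            # bp, 1 for SNV
    vaf: float             # variant allele fraction in (0, 1]

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise ValidationError(f"unknown vtype {self.vtype!r}")
        if self.position < 1:
            raise ValidationError("position must be >= 1")
        if self.length < 1:
            raise ValidationError("length must be >= 1")
        if not 0.0 < self.vaf <= 1.0:
            raise ValidationError("vaf must be in (0, 1]")


@dataclass(frozen=True)
class SiteFeatures:
    """Sequencing evidence at one genomic site."""

    depth_ratio: float       # local depth / expected depth, >= 0
    insert_z: float          # standardized insert-size shift
    split_frac: float        # fraction of split reads, [0, 1]
    mismatch_frac: float     # fraction of mismatching bases, [0, 1]
    orientation_flag: bool   # inverted-orientation evidence

    def __post_init__(self) -> None:
        if self.depth_ratio < 0:
            raise ValidationError("depth_ratio must be >= 0")
        for name in ("split_frac", "mismatch_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SampleSpec:
    """Recipe for one synthetic sample.

    ``composition`` follows the :data:`VTYPES` order (SNV, INS, DEL, INV,
    DUP) and must sum to 1.  ``vaf_range`` bounds the uniform law the variant
    allele fractions are drawn from; the default lower bound of 0.2 keeps the
    noise-free feature signatures of all five types separable by the default
    rule thresholds.
    """

    n_variants: int = 500
    composition: tuple[float, ...] = (0.70, 0.15, 0.15, 0.0, 0.0)
    region_size_mb: float = 1.0
    seq_noise: SeqNoise = field(default_factory=SeqNoise)
    seed: int = 0
    vaf_range: tuple[float, float] = (0.2, 1.0)
    n_background: int = 2000

    def validate(self) -> None:
        if self.n_variants < 0:
            raise ValidationError("n_variants must be >= 0")
        if self.n_background < 0:
            raise ValidationError("n_background must be >= 0")
        if self.region_size_mb <= 0:
            raise ValidationError("region_size_mb must be > 0")
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (len(VTYPES),):
            raise ValidationError(
                f"composition must have {len(VTYPES)} entries (order {VTYPES})")
        if (comp < 0).any():
            raise ValidationError("composition entries must be >= 0")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValidationError("composition must sum to 1 within 1e-9")
        lo, hi = self.vaf_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError("vaf_range must satisfy 0 < lo <= hi <= 1")
        self.seq_noise.validate()

    @property
    def region_length(self) -> int:
        return int(round(self.region_size_mb * 1e6))


@dataclass
class SyntheticSample:
    """A truth set plus the evidence vectors at variant and background sites.

    Background sites are the non-variant positions a caller also inspects;
    they are the source of false positives.  ``background_positions[j]``
    aligns one-to-one with ``background_features[j]``.
    """

    spec: SampleSpec
    sample_id: str
    truth: list[VariantRecord]
    variant_features: list[SiteFeatures]
    background_features: list[SiteFeatures]
    background_positions: np.ndarray

    def __post_init__(self) -> None:
        if len(self.truth) != len(self.variant_features):
            raise ValidationError("truth and variant_features must align")
        if len(self.background_features) != len(self.background_positions):
            raise ValidationError(
                "background_features and background_positions must align")
        ids = [v.site_id for v in self.truth]
        if len(set(ids)) != len(ids):
            raise ValidationError("site_ids must be unique within a sample")

    @property
    def n_background(self) -> int:
        return len(self.background_features)


# ---------------------------------------------------------------------------
# feature generative model
# ---------------------------------------------------------------------------

def feature_location(vtype: str, vaf: float, noise: SeqNoise) -> dict:
    """Type-conditional feature locations (the noise-free signature).

    Returns the lognormal median of ``depth_ratio``, the mean of
    ``insert_z``, the means of ``split_frac``/``mismatch_frac`` and the
    probability of orientation evidence.  Dispersion around these locations
    is governed separately by *noise* (see :func:`simulate_site_features`).
    """
    s = noise.scale
    loc = {
        "depth_ratio": 1.0,
        "insert_z": 0.0,
        "split_frac": 0.0,
        "mismatch_frac": s * noise.background_mismatch,
        "orientation_p": min(1.0, s * noise.orient_error),
    }
    if vtype == "SNV":
        loc["mismatch_frac"] = vaf
    elif vtype == "DEL":
        loc["depth_ratio"] = 1.0 - 0.45 * vaf
        loc["insert_z"] = 3.0 * vaf
        loc["split_frac"] = 0.5 * vaf
    elif vtype == "INS":
        loc["insert_z"] = -3.0 * vaf
        loc["split_frac"] = 0.5 * vaf
    elif vtype == "INV":
        loc["split_frac"] = 0.5 * vaf
        loc["orientation_p"] = max(0.0, 1.0 - s * noise.inv_miss)
    elif vtype == "DUP":
        loc["depth_ratio"] = 1.0 + 0.6 * vaf
        loc["split_frac"] = 0.4 * vaf
    else:  # pragma: no cover - guarded by VariantRecord validation
        raise ValidationError(f"unknown vtype {vtype!r}")
    return loc


def fraction_noise_sd(mean: float, noise: SeqNoise) -> float:
    """Effective SD of a fraction feature with the given mean.

    The nominal SD ``scale * frac_sd`` is clamped so the matched beta
    distribution keeps positive shape parameters.
    """
    if mean <= 0.0 or mean >= 1.0:
        return 0.0
    sd = noise.scale * noise.frac_sd
    return float(min(sd, 0.5 * np.sqrt(mean * (1.0 - mean))))


def fraction_beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters (a, b) with the given mean and SD."""
    if not 0.0 < mean < 1.0:
        raise ValidationError("beta mean must be in (0, 1)")
    if sd <= 0:
        raise ValidationError("beta sd must be > 0")
    k = mean * (1.0 - mean) / sd**2 - 1.0
    if k <= 0:
        raise ValidationError("sd too large for a beta with this mean")
    return mean * k, (1.0 - mean) * k


def _draw_fraction(mean: float, noise: SeqNoise, rng: np.random.Generator) -> float:
    sd = fraction_noise_sd(mean, noise)
    if sd == 0.0:
        return float(np.clip(mean, 0.0, 1.0))
    a, b = fraction_beta_params(mean, sd)
    return float(rng.beta(a, b))


def _draw_features(vtype: str, vaf: float, noise: SeqNoise,
                   rng: np.random.Generator) -> SiteFeatures:
    loc = feature_location(vtype, vaf, noise)
    s = noise.scale
    sig_d = s * noise.depth_sigma
    depth = loc["depth_ratio"] * float(np.exp(rng.normal(0.0, sig_d))) \
        if sig_d > 0 else loc["depth_ratio"]
    sig_z = s * noise.insert_sigma
    insert_z = float(rng.normal(loc["insert_z"], sig_z)) if sig_z > 0 \
        else loc["insert_z"]
    split = _draw_fraction(loc["split_frac"], noise, rng)
    mism = _draw_fraction(loc["mismatch_frac"], noise, rng)
    orient = bool(rng.random() < loc["orientation_p"])
    return SiteFeatures(depth_ratio=depth, insert_z=insert_z,
                        split_frac=split, mismatch_frac=mism,
                        orientation_flag=orient)


def simulate_site_features(variant: VariantRecord, seq_noise: SeqNoise,
                           rng: np.random.Generator) -> SiteFeatures:
    """Draw the evidence vector at a variant site.

    In the noise-free limit the draw equals the type signature of
    :func:`feature_location` exactly.
    """
    seq_noise.validate()
    return _draw_features(variant.vtype, variant.vaf, seq_noise, rng)


def simulate_background_sites(n: int, seq_noise: SeqNoise,
                              rng: np.random.Generator) -> list[SiteFeatures]:
    """Draw evidence vectors for ``n`` sites carrying no variant."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    seq_noise.validate()
    s = seq_noise.scale
    out = []
    for _ in range(n):
        sig_d = s * seq_noise.depth_sigma
        depth = float(np.exp(rng.normal(0.0, sig_d))) if sig_d > 0 else 1.0
        sig_z = s * seq_noise.insert_sigma
        insert_z = float(rng.normal(0.0, sig_z)) if sig_z > 0 else 0.0
        split = _draw_fraction(s * seq_noise.background_split, seq_noise, rng)
        mism = _draw_fraction(s * seq_noise.background_mismatch, seq_noise, rng)
        orient = bool(rng.random() < s * seq_noise.orient_error)
        out.append(SiteFeatures(depth, insert_z, split, mism, orient))
    return out


# ---------------------------------------------------------------------------
# planting and sample synthesis
# ---------------------------------------------------------------------------

def plant_variants(spec: SampleSpec,
                   rng: np.random.Generator) -> list[VariantRecord]:
    """Plant ``spec.n_variants`` variants at distinct uniform positions.

    Per-type counts are multinomial on ``spec.composition``; positions are
    distinct and uniform over the region; the type sequence is shuffled so
    position order carries no type information.
    """
    spec.validate()
    n = spec.n_variants
    region = spec.region_length
    if n > region:
        raise CapacityError(
            f"region of {region} bp cannot host {n} distinct variant positions")
    if n == 0:
        return []
    comp = np.asarray(spec.composition, dtype=float)
    counts = rng.multinomial(n, comp)
    types = np.repeat(np.array(VTYPES, dtype=object), counts)
    rng.shuffle(types)
    positions = np.sort(rng.choice(region, size=n, replace=False)) + 1
    lo, hi = spec.vaf_range
    vafs = rng.uniform(lo, hi, size=n)
    records = []
    for i in range(n):
        vt = str(types[i])
        if vt == "SNV":
            length = 1
        elif vt in ("INS", "DEL"):
            length = int(rng.integers(1, 51))
        else:  # INV / DUP: larger structural events
            length = int(rng.integers(50, 501))
        records.append(VariantRecord(site_id=i, position=int(positions[i]),
                                     vtype=vt, length=length,
                                     vaf=float(vafs[i])))
    return records


def synthesize_sample(spec: SampleSpec, rng: np.random.Generator | None = None,
                      sample_id: str = "S00") -> SyntheticSample:
    """Build one full sample: truth set, variant features, background sites."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    truth = plant_variants(spec, rng)
    vfeat = [simulate_site_features(v, spec.seq_noise, rng) for v in truth]

    region = spec.region_length
    if spec.n_variants + spec.n_background > region:
        raise CapacityError("region too small for variant + background sites")
    taken = {v.position for v in truth}
    bg_positions: list[int] = []
    while len(bg_positions) < spec.n_background:
        need = spec.n_background - len(bg_positions)
        batch = rng.integers(1, region + 1, size=max(need * 2, 16))
        for p in batch:
            p = int(p)
            if p not in taken:
                taken.add(p)
                bg_positions.append(p)
                if len(bg_positions) == spec.n_background:
                    break
    bfeat = simulate_background_sites(spec.n_background, spec.seq_noise, rng)
    return SyntheticSample(spec=spec, sample_id=sample_id, truth=truth,
                           variant_features=vfeat, background_features=bfeat,
                           background_positions=np.asarray(bg_positions))


def _heterogeneous_composition(base: np.ndarray, rng: np.random.Generator,
                               indel_range: tuple[float, float]) -> tuple[float, ...]:
    # Vary the combined INS+DEL fraction; split indels and non-indels in the
    # base proportions (equal / all-SNV when the base gives no guidance).
    f = float(rng.uniform(*indel_range))
    indel = base[[1, 2]]
    other = base[[0, 3, 4]]
    indel_split = indel / indel.sum() if indel.sum() > 0 else np.array([0.5, 0.5])
    other_split = other / other.sum() if other.sum() > 0 else np.array([1.0, 0.0, 0.0])
    comp = np.empty(5)
    comp[[1, 2]] = f * indel_split
    comp[[0, 3, 4]] = (1.0 - f) * other_split
    return tuple(float(x) for x in comp)


def make_cohort(n_samples: int, composition_mode: str, base_spec: SampleSpec,
                master_seed: int | None = None,
                indel_range: tuple[float, float] = (0.0, 0.6)
                ) -> list[SyntheticSample]:
    """Generate a cohort of samples from one master seed.

    ``homogeneous`` copies the base composition to every sample;
    ``heterogeneous`` draws each sample's combined INS+DEL fraction uniformly
    from ``indel_range`` — the mutation-composition shift that destabilizes a
    caller whose rules cover only part of the type spectrum.  Per-sample
    random streams are derived by keyed hashing of the master seed and the
    sample index, so cohorts are reproducible and the streams independent.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if composition_mode not in ("heterogeneous", "homogeneous"):
        raise ValidationError(
            f"unknown composition_mode {composition_mode!r}")
    base_spec.validate()
    master = base_spec.seed if master_seed is None else master_seed
    base = np.asarray(base_spec.composition, dtype=float)
    samples = []
    for i in range(n_samples):
        comp_rng = np.random.default_rng(
            np.random.SeedSequence(master, spawn_key=(i, 1)))
        if composition_mode == "heterogeneous":
            comp = _heterogeneous_composition(base, comp_rng, indel_range)
        else:
            comp = tuple(float(x) for x in base)
        ss = np.random.SeedSequence(master, spawn_key=(i, 0))
        child_seed = int(ss.generate_state(1)[0])
        spec_i = replace(base_spec, composition=comp, seed=child_seed)
        rng = np.random.default_rng(ss)
        samples.append(synthesize_sample(spec_i, rng=rng,
                                         sample_id=f"S{i:02d}"))
    return samples


# ---------------------------------------------------------------------------
# output: minimal VCF 4.2 / CSV / manifest
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chrS,length={length}>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of planted variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant in bp">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INV,Description="Inversion">
##ALT=<ID=DUP,Description="Tandem duplication">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _vcf_line(v: VariantRecord, filter_field: str = "PASS") -> str:
    if v.vtype == "SNV":
        ref, alt, svlen = "N", "A", 1
    else:
        ref, alt = "N", f"<{v.vtype}>"
        svlen = -v.length if v.vtype == "DEL" else v.length
    info = f"SVTYPE={v.vtype};SVLEN={svlen};VAF={v.vaf:.4f}"
    return (f"chrS\t{v.position}\tsite{v.site_id}\t{ref}\t{alt}\t.\t"
            f"{filter_field}\t{info}\n")


def write_truth_vcf(sample: SyntheticSample, path) -> None:
    """Write the truth set as a minimal, sorted VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(length=sample.spec.region_length))
        for v in sorted(sample.truth, key=lambda r: r.position):
            fh.write(_vcf_line(v))


def write_truth_csv(sample: SyntheticSample, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["site_id", "position", "vtype", "length", "vaf"])
        for v in sample.truth:
            w.writerow([v.site_id, v.position, v.vtype, v.length,
                        f"{v.vaf:.6f}"])


def write_cohort_manifest(samples: Sequence[SyntheticSample], path) -> None:
    """JSON manifest of per-sample specs (composition, seed, sizes)."""
    entries = []
    for s in samples:
        entries.append({
            "sample_id": s.sample_id,
            "n_variants": s.spec.n_variants,
            "n_background": s.spec.n_background,
            "region_size_mb": s.spec.region_size_mb,
            "composition": dict(zip(VTYPES, s.spec.composition)),
            "seed": s.spec.seed,
        })
    with open(path, "w") as fh:
        json.dump({"samples": entries}, fh, indent=2)
        fh.write("\n")
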