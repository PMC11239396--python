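"""Synthetic multi-modal case-control cohorts.

Generates paired subject-level data for the three modalities the pipeline
consumes — grey-matter density volumes, functional network connectivity
(FNC) matrices from a 53-component decomposition, and additive SNP dosages
— together with binary diagnosis labels and the planted ground truth, so
every downstream stage (encoding, relevance ranking, selection, fusion,
cross-validation) can be exercised and audited without any external data.

Generative model
----------------
* SNPs: per-SNP minor-allele frequency drawn uniformly from ``maf_range``;
  dosages from Hardy-Weinberg proportions (Binomial(2, MAF)). Labels come
  from a logistic model over the planted SNPs (allele-centred, intercept
  logit(case_fraction)), so with no planted SNPs labels are simply
  Bernoulli(case_fraction).
* FNC: each connection has a cohort-level baseline mean in Fisher-z space;
  subject values add Gaussian noise (``noise_sd``) and, for cases, the
  planted mean shift; the inverse Fisher transform maps entries into
  (-1, 1). Matrices are exactly symmetric with unit diagonal.
* Volumes: a constant-density background plus voxel-wise Gaussian noise;
  cases additionally receive the configured density shift inside each
  planted region box; values are clipped to [0, 1].

Signals are planted conditionally on the label (discriminative planting),
which makes case-control differences directly recoverable by a per-feature
group-difference scan — the brute-force oracle used to validate relevance
rankings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DOMAIN_PARTITION",
    "CohortConfig",
    "SyntheticCohort",
    "default_domain_map",
    "simulate_snps",
    "simulate_fnc",
    "simulate_volumes",
    "simulate_cohort",
    "group_difference_scan",
    "write_cohort",
    "read_cohort",
]

#: Default assignment of the 53 ICA components to intrinsic connectivity
#: network domains (subcortical, auditory, sensorimotor, visual,
#: cognitive-control, default-mode, cerebellar), following the standard
#: 53-component template partition. Sizes sum to 53.
DOMAIN_PARTITION = {
    "SC": 5,
    "AUD": 2,
    "SM": 9,
    "VIS": 9,
    "CC": 17,
    "DM": 7,
    "CB": 4,
}


def default_domain_map(n_components=53):
    """Domain label per component; the 53-component default partition is
    stretched proportionally for other component counts."""
    sizes = list(DOMAIN_PARTITION.values())
    names = list(DOMAIN_PARTITION)
    if n_components == sum(sizes):
        counts = sizes
    else:
        counts = [max(1, round(s * n_components / sum(sizes))) for s in sizes]
        while sum(counts) > n_components:
            counts[int(np.argmax(counts))] -= 1
        while sum(counts) < n_components:
            counts[int(np.argmin(counts))] += 1
    out = []
    for name, c in zip(names, counts):
        out.extend([name] * c)
    return out[:n_components]


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort; defaults mirror the target data
    scale (53 components -> 1378 connections, 4943 SNPs, 121x145x121
    voxel grey-matter maps)."""

    n_subjects: int = 200
    case_fraction: float = 0.5
    volume_shape: tuple = (121, 145, 121)
    n_components: int = 53
    n_snps: int = 4943
    fnc_effect: list = field(default_factory=list)  # (connection_idx, z shift)
    snp_effect: list = field(default_factory=list)  # (snp_idx, log-odds/allele)
    volume_effect: list = field(default_factory=list)  # (box, density shift)
    maf_range: tuple = (0.05, 0.5)
    noise_sd: float = 0.2
    seed: int = 0

    @property
    def n_connections(self):
        return self.n_components * (self.n_components - 1) // 2

    def validate(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.case_fraction * self.n_subjects < 1:
            raise ValueError("expected case count below 1 subject")
        if len(self.volume_shape) != 3 or any(s < 8 for s in self.volume_shape):
            raise ValueError("volume_shape must be 3 integers, each >= 8")
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for idx, _ in self.fnc_effect:
            if not 0 <= idx < self.n_connections:
                raise ValueError(
                    f"planted FNC connection {idx} outside "
                    f"[0, {self.n_connections})"
                )
        for idx, _ in self.snp_effect:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"planted SNP {idx} outside [0, {self.n_snps})")
        for box, _ in self.volume_effect:
            if len(box) != 3:
                raise ValueError("region box must have 3 (start, stop) pairs")
            for (lo, hi), dim in zip(box, self.volume_shape):
                if not 0 <= lo < hi <= dim:
                    raise ValueError(f"region box {box} outside volume_shape")
        return self


@dataclass
class SyntheticCohort:
    subject_ids: list
    volumes: np.ndarray  # (n, dz, dy, dx), float32 in [0, 1]
    fnc: np.ndarray  # (n, c, c), symmetric, unit diagonal
    snps: np.ndarray  # (n, n_snps), int8 dosages in {0, 1, 2}
    labels: np.ndarray  # (n,), 1 = case
    truth: dict  # planted-effect lists keyed by modality
    domain_map: list  # domain per component
    snp_ids: list  # rs-style identifiers per SNP
    config: CohortConfig | None = None


def _rng_for(config, stream):
    # independent deterministic streams per modality
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_snps(config: CohortConfig):
    """Dosage matrix + labels + planted truth.

    Genotypes follow Hardy-Weinberg proportions at per-SNP MAFs; labels are
    drawn from a logistic model whose per-allele log-odds are non-zero only
    on planted SNPs.
    """
    config.validate()
    rng = _rng_for(config, 1)
    n, s = config.n_subjects, config.n_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=s)
    dosages = rng.binomial(2, maf, size=(n, s)).astype(np.int8)
    eta = np.full(n, _logit(config.case_fraction))
    for idx, beta in config.snp_effect:
        eta += beta * (dosages[:, idx] - 2 * maf[idx])
    labels = (rng.random(n) < _sigmoid(eta)).astype(np.int8)
    # degenerate single-class draws are re-balanced deterministically
    if labels.min() == labels.max():
        labels[: max(1, n // 2)] = 1 - labels[0]
    truth = {"snp": list(config.snp_effect)}
    return dosages, labels, truth


def simulate_fnc(config: CohortConfig, labels):
    """Per-subject symmetric FNC matrices with unit diagonal.

    Connection values are sampled in Fisher-z space (baseline + noise +
    planted case shift) then mapped through tanh into (-1, 1).
    """
    config.validate()
    labels = np.asarray(labels)
    if len(labels) != config.n_subjects:
        raise ValueError("labels length must equal n_subjects")
    rng = _rng_for(config, 2)
    n, c, k = config.n_subjects, config.n_components, config.n_connections
    baseline = rng.normal(0.0, 0.3, size=k)
    z = baseline[None, :] + rng.normal(0.0, config.noise_sd, size=(n, k))
    for idx, shift in config.fnc_effect:
        z[:, idx] += shift * labels
    r = np.tanh(z)
    fnc = np.zeros((n, c, c))
    rows, cols = lower_triangle_indices(c)
    fnc[:, rows, cols] = r
    fnc[:, cols, rows] = r
    fnc[:, np.arange(c), np.arange(c)] = 1.0
    truth = {"fnc": list(config.fnc_effect)}
    return fnc, truth


def simulate_volumes(config: CohortConfig, labels):
    """Per-subject 3D grey-matter density arrays, clipped to [0, 1]."""
    config.validate()
    labels = np.asarray(labels)
    if len(labels) != config.n_subjects:
        raise ValueError("labels length must equal n_subjects")
    rng = _rng_for(config, 3)
    shape = tuple(config.volume_shape)
    n = config.n_subjects
    vols = np.empty((n,) + shape, dtype=np.float32)
    for i in range(n):  # per-subject draw keeps peak memory flat
        v = 0.5 + rng.normal(0.0, config.noise_sd, size=shape)
        if labels[i]:
            for box, shift in config.volume_effect:
                sl = tuple(slice(lo, hi) for lo, hi in box)
                v[sl] += shift
        np.clip(v, 0.0, 1.0, out=v)
        vols[i] = v
    return vols


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full cohort: SNPs (which define the labels), then FNC and volumes
    conditioned on those labels."""
    config.validate()
    snps, labels, snp_truth = simulate_snps(config)
    fnc, fnc_truth = simulate_fnc(config, labels)
    volumes = simulate_volumes(config, labels)
    truth = {**snp_truth, **fnc_truth, "volume": list(config.volume_effect)}
    subject_ids = [f"sub-{i:04d}" for i in range(config.n_subjects)]
    snp_ids = [f"rs{1000000 + i}" for i in range(config.n_snps)]
    return SyntheticCohort(
        subject_ids=subject_ids,
        volumes=volumes,
        fnc=fnc,
        snps=snps,
        labels=labels.astype(np.int8),
        truth=truth,
        domain_map=default_domain_map(config.n_components),
        snp_ids=snp_ids,
        config=config,
    )


def lower_triangle_indices(n_components):
    """Row-major enumeration of the strict lower triangle: (row, col) with
    row > col, ordered by row then column."""
    rows, cols = np.tril_indices(n_components, k=-1)
    return rows, cols


def group_difference_scan(features, labels):
    """Brute-force oracle: |case mean - control mean| per feature."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not labels.any() or labels.all():
        raise ValueError("both groups must be non-empty")
    return np.abs(features[labels].mean(axis=0) - features[~labels].mean(axis=0))


def _logit(p):
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# --------------------------------------------------------------------------
# serialization


def write_cohort(cohort: SyntheticCohort, directory):
    """Serialize a cohort: NIfTI volumes, one CSV per FNC matrix, a PLINK
    .raw-dialect dosage table, and a manifest CSV tying them together."""
    import nibabel as nib

    directory = Path(directory)
    (directory / "volumes").mkdir(parents=True, exist_ok=True)
    (directory / "fnc").mkdir(exist_ok=True)
    manifest_rows = []
    for i, sid in enumerate(cohort.subject_ids):
        vol_path = directory / "volumes" / f"{sid}.nii.gz"
        nib.save(
            nib.Nifti1Image(cohort.volumes[i].astype(np.float32), np.eye(4)),
            str(vol_path),
        )
        fnc_path = directory / "fnc" / f"{sid}.csv"
        np.savetxt(fnc_path, cohort.fnc[i], delimiter=",", fmt="%.10g")
        manifest_rows.append(
            {
                "subject_id": sid,
                "label": int(cohort.labels[i]),
                "volume_path": str(vol_path.relative_to(directory)),
                "fnc_path": str(fnc_path.relative_to(directory)),
            }
        )
    # PLINK .raw dialect: 6 pedigree columns, then one dosage column per SNP;
    # PHENOTYPE is coded 1=control, 2=case
    with open(directory / "snps.raw", "w") as fh:
        header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        header += [f"{rs}_A" for rs in cohort.snp_ids]
        fh.write(" ".join(header) + "\n")
        for i, sid in enumerate(cohort.subject_ids):
            row = [sid, sid, "0", "0", "0", str(int(cohort.labels[i]) + 1)]
            row += [str(int(d)) for d in cohort.snps[i]]
            fh.write(" ".join(row) + "\n")
    with open(directory / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["subject_id", "label", "volume_path", "fnc_path"]
        )
        writer.writeheader()
        writer.writerows(manifest_rows)
    with open(directory / "domain_map.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["component", "domain"])
        for comp, dom in enumerate(cohort.domain_map):
            writer.writerow([comp, dom])
    with open(directory / "truth.yaml", "w") as fh:
        yaml.safe_dump(_jsonable(cohort.truth), fh)
    return directory


def read_cohort(directory) -> SyntheticCohort:
    """Inverse of :func:`write_cohort`; validates cross-modality consistency."""
    import nibabel as nib

    directory = Path(directory)
    with open(directory / "manifest.csv", newline="") as fh:
        manifest = list(csv.DictReader(fh))
    if not manifest:
        raise ValueError("manifest lists no subjects")
    subject_ids = [row["subject_id"] for row in manifest]
    labels = np.array([int(row["label"]) for row in manifest], dtype=np.int8)

    volumes, fnc = [], []
    for row in manifest:
        for key in ("volume_path", "fnc_path"):
            if not (directory / row[key]).exists():
                raise FileNotFoundError(
                    f"manifest entry missing on disk: {row[key]}"
                )
        volumes.append(
            np.asarray(
                nib.load(str(directory / row["volume_path"])).dataobj,
                dtype=np.float32,
            )
        )
        fnc.append(np.loadtxt(directory / row["fnc_path"], delimiter=","))

    with open(directory / "snps.raw") as fh:
        header = fh.readline().split()
        if header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
            raise ValueError("malformed PLINK .raw header")
        snp_ids = [c.rsplit("_", 1)[0] for c in header[6:]]
        rows = [line.split() for line in fh if line.strip()]
    if len(rows) != len(manifest):
        raise ValueError(
            f"subject count mismatch: manifest has {len(manifest)}, "
            f".raw has {len(rows)}"
        )
    snps = np.array([[int(v) for v in r[6:]] for r in rows], dtype=np.int8)
    raw_labels = np.array([int(r[5]) - 1 for r in rows], dtype=np.int8)
    if not np.array_equal(raw_labels, labels):
        raise ValueError("PHENOTYPE column disagrees with manifest labels")

    with open(directory / "domain_map.csv", newline="") as fh:
        domain_map = [row["domain"] for row in csv.DictReader(fh)]
    truth_path = directory / "truth.yaml"
    truth = yaml.safe_load(truth_path.read_text()) if truth_path.exists() else {}
    return SyntheticCohort(
        subject_ids=subject_ids,
        volumes=np.stack(volumes),
        fnc=np.stack(fnc),
        snps=snps,
        labels=labels,
        truth=truth,
        domain_map=domain_map,
        snp_ids=snp_ids,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
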