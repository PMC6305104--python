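"""Synthetic paired tumor/normal datasets with known ground truth.

The generator emulates the study design the pipeline targets: subjects each
contribute a carcinoma and a normal-mucosa sample; RNA-Seq counts follow a
negative binomial with a per-subject random intercept and a library-size
exposure; miRNA array signals carry per-sample multiplicative distortions
that the 75th-percentile normalization is meant to remove; planted
(gene, miRNA) pairs co-vary at the subject-differential level with a chosen
standardized slope; planted UTR seed sites are inserted at recorded
positions. Every planted effect is recorded in :class:`GroundTruth` so each
downstream stage can be scored exactly.

One root seed drives four deterministic substreams (counts, signals, UTRs,
metadata), so regenerating any one stage is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import PairedExpressionSet
from .seeds import MatureMiRNA, UTRRecord, site_patterns

_STREAMS = {"counts": 0, "signals": 1, "utrs": 2, "metadata": 3, "catalog": 4}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-level simulation parameters.

    Per-gene fields (``baseline_log_mean``, ``tumor_log_fc``, ``dispersion``)
    accept a scalar (broadcast) or an array of length ``n_genes``.
    ``baseline_log_mean`` is the log relative abundance (log fraction of the
    library); ``tumor_log_fc`` is on the natural-log scale; ``dispersion`` is
    the NB size parameter theta. ``planted_beta`` maps (gene_id, mirna_id) to
    the standardized slope linking the pair's subject-level differentials.
    Cohort-style defaults follow the targeted study population: 217 subjects,
    age Normal(64.8, 10.1), 54.4% male, 13.4% microsatellite-unstable.
    """

    n_subjects: int = 217
    n_genes: int = 200
    n_mirnas: int = 100
    baseline_log_mean: float | np.ndarray = -9.0
    tumor_log_fc: float | np.ndarray = 0.0
    dispersion: float | np.ndarray = 5.0
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    subject_sd: float = 0.3
    array_scale_range: tuple[float, float] = (0.5, 2.0)
    planted_beta: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 1.0
    utr_length: int = 2000
    utr_gc: float = 0.5
    seed: int = 0
    # miRNA signal shape and cohort covariates
    mirna_log_mean: float = 2.0
    mirna_log_sd: float = 1.0
    mirna_subject_sd: float = 0.5
    mirna_diff_scale: float = 0.5
    mirna_tumor_shift: float = 1.5
    msi_prop: float = 0.134
    male_prop: float = 0.544
    age_mean: float = 64.8
    age_sd: float = 10.1

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_genes", "n_mirnas"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        if np.any(self._per_gene(self.dispersion) <= 0):
            raise ConfigurationError("dispersion (NB size theta) must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("library_size_range must be ordered positive integers")
        a, b = self.array_scale_range
        if not (0 < a <= b):
            raise ConfigurationError("array_scale_range must be ordered positive reals")
        if self.subject_sd < 0 or self.noise_sd <= 0:
            raise ConfigurationError("subject_sd must be >= 0 and noise_sd > 0")
        if self.utr_length <= 0:
            raise ConfigurationError("utr_length must be positive")
        genes, mirnas = set(self.gene_ids), set(self.mirna_ids)
        for g, m in self.planted_beta:
            if g not in genes or m not in mirnas:
                raise ConfigurationError(f"planted pair ({g}, {m}) references unknown IDs")

    # -- identifiers -------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def mirna_ids(self) -> list[str]:
        return [f"hsa-miR-{1000 + i}" for i in range(self.n_mirnas)]

    @property
    def subject_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_subjects)]

    def sample_ids(self) -> tuple[list[str], list[str]]:
        """(normal sample IDs, carcinoma sample IDs), subject order."""
        return [f"{s}-N" for s in self.subject_ids], [f"{s}-T" for s in self.subject_ids]

    def _per_gene(self, x) -> np.ndarray:
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 0:
            return np.full(self.n_genes, float(arr))
        if arr.shape != (self.n_genes,):
            raise ConfigurationError(f"per-gene field has shape {arr.shape}, expected ({self.n_genes},)")
        return arr

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class GroundTruth:
    """Planted effects, recorded once each."""

    true_de_genes: set[str] = field(default_factory=set)
    true_log_fc: dict[str, float] = field(default_factory=dict)
    planted_associations: list[tuple[str, str, float]] = field(default_factory=list)
    planted_sites: list[tuple[str, str, int, str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["true_de_genes"] = sorted(self.true_de_genes)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            true_de_genes=set(d["true_de_genes"]),
            true_log_fc=d["true_log_fc"],
            planted_associations=[tuple(t) for t in d["planted_associations"]],
            planted_sites=[tuple(t) for t in d["planted_sites"]],
        )


def _pair_metadata(config: SimulationConfig):
    normal_ids, tumor_ids = config.sample_ids()
    samples = [s for pair in zip(normal_ids, tumor_ids) for s in pair]
    subject_of = pd.Series(
        {s: s.rsplit("-", 1)[0] for s in samples}, name="subject_id"
    )
    tissue_of = pd.Series(
        {s: ("normal" if s.endswith("-N") else "carcinoma") for s in samples}, name="tissue"
    )
    return samples, subject_of, tissue_of


def simulate_paired_counts(config: SimulationConfig) -> tuple[PairedExpressionSet, GroundTruth]:
    """NB counts for a paired design; returns the data and its ground truth.

    For subject i and tissue t the count of gene g is NB with mean
    ``exp(baseline_g + lfc_g * [t=carcinoma] + u_i) * libsize_it`` and size
    ``theta_g``, with u_i ~ Normal(0, subject_sd).
    """
    rng = config.rng("counts")
    base = config._per_gene(config.baseline_log_mean)
    lfc = config._per_gene(config.tumor_log_fc)
    theta = config._per_gene(config.dispersion)
    n, G = config.n_subjects, config.n_genes

    u = rng.normal(0.0, config.subject_sd, size=n)
    lo, hi = config.library_size_range
    libsize = rng.integers(lo, hi + 1, size=(n, 2))  # col 0 normal, col 1 tumor

    samples, subject_of, tissue_of = _pair_metadata(config)
    log_mu = (
        base[:, None, None]
        + lfc[:, None, None] * np.array([0.0, 1.0])[None, None, :]
        + u[None, :, None]
        + np.log(libsize)[None, :, :]
    )  # (G, n, 2)
    mu = np.exp(log_mu)
    p = theta[:, None, None] / (theta[:, None, None] + mu)
    counts = rng.negative_binomial(theta[:, None, None], p, size=(G, n, 2))

    # interleave as N, T per subject to match sample order
    mat = np.empty((G, 2 * n), dtype=np.int64)
    mat[:, 0::2] = counts[:, :, 0]
    mat[:, 1::2] = counts[:, :, 1]
    values = pd.DataFrame(mat, index=pd.Index(config.gene_ids, name="feature_id"), columns=samples)

    truth = GroundTruth(
        true_de_genes={g for g, f in zip(config.gene_ids, lfc) if f != 0},
        true_log_fc=dict(zip(config.gene_ids, lfc.tolist())),
        planted_associations=[(g, m, b) for (g, m), b in sorted(config.planted_beta.items())],
    )
    return PairedExpressionSet(values, subject_of, tissue_of), truth


def simulate_mirna_signals(
    config: SimulationConfig, truth: GroundTruth, counts: PairedExpressionSet
) -> PairedExpressionSet:
    """Array-style miRNA signals whose planted pairs track the mRNA differentials.

    For a planted (gene, miRNA, beta), the miRNA's subject-level differential
    is ``scale * (beta * z + noise_sd * eps)`` where ``z`` is the z-scored
    RPMPCG differential of the gene, so with ``noise_sd = sqrt(1 - beta^2)``
    the population standardized slope equals ``beta``. Unplanted miRNAs get
    pure noise differentials. Signals are kept non-negative by lifting the
    normal-tissue baseline rather than clipping, which would bias the planted
    slope. Finally every sample is multiplied by a distortion drawn uniformly
    from ``array_scale_range`` (the artefact the Q75 scaling removes).
    """
    rng = config.rng("signals")
    n, M = config.n_subjects, config.n_mirnas

    # z-scored RPMPCG differentials of planted genes
    totals = counts.values.sum(axis=0).astype(float)
    rpm = counts.values.div(totals, axis=1) * 1e6
    carc = rpm[counts.samples_of("carcinoma")].to_numpy()
    norm = rpm[counts.samples_of("normal")].to_numpy()
    d_gene = carc - norm  # (G, n), subject order
    gene_pos = {g: i for i, g in enumerate(counts.feature_ids)}
    zscores = {}
    for g in {g for g, _, _ in truth.planted_associations}:
        d = d_gene[gene_pos[g]]
        sd = d.std(ddof=1)
        zscores[g] = (d - d.mean()) / (sd if sd > 0 else 1.0)

    planted_by_mirna: dict[str, list[tuple[str, float]]] = {}
    for g, m, b in truth.planted_associations:
        planted_by_mirna.setdefault(m, []).append((g, b))

    baseline = np.exp(rng.normal(config.mirna_log_mean, config.mirna_log_sd, size=M))
    base_subject = baseline[:, None] * np.exp(rng.normal(0.0, config.mirna_subject_sd, size=(M, n)))
    eps = rng.normal(0.0, 1.0, size=(M, n))

    d_mirna = np.empty((M, n))
    for j, m in enumerate(config.mirna_ids):
        signal = config.noise_sd * eps[j]
        if m in planted_by_mirna:
            # planted miRNAs are themselves differentially expressed, as the
            # reporting filter (miRNA FC outside 0.67-1.50) presumes
            signal = signal + config.mirna_tumor_shift
            for g, b in planted_by_mirna[m]:
                signal = signal + b * zscores[g]
        d_mirna[j] = config.mirna_diff_scale * baseline[j] * signal

    normal_vals = base_subject + np.maximum(0.0, -d_mirna)
    tumor_vals = normal_vals + d_mirna

    samples, subject_of, tissue_of = _pair_metadata(config)
    mat = np.empty((M, 2 * n))
    mat[:, 0::2] = normal_vals
    mat[:, 1::2] = tumor_vals
    a, b = config.array_scale_range
    distortion = rng.uniform(a, b, size=2 * n)
    mat = mat * distortion[None, :]
    values = pd.DataFrame(mat, index=pd.Index(config.mirna_ids, name="feature_id"), columns=samples)
    return PairedExpressionSet(values, subject_of, tissue_of)


def simulate_mirna_catalog(
    config: SimulationConfig, length: int = 22, clean_compatible: bool = False, mode: str = "literal"
) -> dict[str, str]:
    """Random mature miRNA sequences (RNA alphabet), miRBase-style names.

    With ``clean_compatible=True`` candidates are redrawn until no miRNA's
    longest site pattern embeds (or equals) any other catalog miRNA's site
    pattern of any length; required so that clean-background UTRs can host a
    planted site without legitimately matching a second miRNA.
    """
    rng = config.rng("catalog")
    alphabet = np.array(list("ACGU"))
    catalog: dict[str, str] = {}
    accepted_patterns: list[list[str]] = []
    for name in config.mirna_ids:
        for _ in range(1000):
            seq = "".join(rng.choice(alphabet, size=length))
            if not clean_compatible:
                break
            mir = MatureMiRNA(name, seq)
            pats = [p for _, p, _ in site_patterns(mir, mode)]
            longest = max(pats, key=len)
            clash = False
            for other in accepted_patterns:
                other_longest = max(other, key=len)
                if any(q in longest for q in other) or any(p in other_longest for p in pats):
                    clash = True
                    break
            if not clash:
                accepted_patterns.append(pats)
                break
        else:
            raise RuntimeError("could not draw a clean-compatible catalog")
        catalog[name] = seq
    return catalog


def simulate_utrs(
    config: SimulationConfig,
    truth: GroundTruth,
    mirna_seqs: dict[str, str],
    mode: str = "literal",
    site_type: str | None = None,
    clean: bool = False,
    site_pairs=None,
) -> tuple[list[UTRRecord], GroundTruth]:
    """Random-background 3' UTRs with planted seed sites; updates ``truth``.

    One UTR per gene (isoform ``utr1``). For each (gene, miRNA) pair in
    ``site_pairs`` (default: the planted associations) the exact
    reverse-complement DNA of the chosen convention's site is written at a
    recorded position. In clean mode the background is repaired (single-base
    mutations inside spurious hits) until no catalog miRNA has a site outside
    the planted windows; see the methods note for why whole-sequence rejection
    sampling is infeasible at realistic lengths.
    """
    rng = config.rng("utrs")
    if site_type is None:
        site_type = "p1-8" if mode == "literal" else "8mer"
    mirnas = {name: MatureMiRNA(name, seq) for name, seq in mirna_seqs.items()}
    pattern_of: dict[str, dict[str, tuple[str, int]]] = {}
    all_patterns: list[str] = []
    for name, mir in mirnas.items():
        pattern_of[name] = {t: (p, off) for t, p, off in site_patterns(mir, mode)}
        all_patterns.extend(p for p, _ in pattern_of[name].values())
    all_patterns = sorted(set(all_patterns))

    if site_pairs is None:
        site_pairs = [(g, m) for g, m, _ in truth.planted_associations]
    by_gene: dict[str, list[str]] = {}
    for g, m in site_pairs:
        if m not in mirnas:
            raise KeyError(f"miRNA {m!r} missing from the sequence catalog")
        by_gene.setdefault(g, []).append(m)

    gc = config.utr_gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    L = config.utr_length

    records: list[UTRRecord] = []
    planted_sites: list[tuple[str, str, int, str]] = []
    for g in config.gene_ids:
        seq = rng.choice(alphabet, size=L, p=probs)
        windows: list[tuple[int, int]] = []
        for m in by_gene.get(g, []):
            pattern, _ = pattern_of[m][site_type]
            if len(pattern) > L:
                raise ValueError(f"utr_length {L} too short to host a {len(pattern)}-nt site")
            for _ in range(1000):
                pos = int(rng.integers(0, L - len(pattern) + 1))
                span = (pos, pos + len(pattern))
                if all(span[1] <= w0 or span[0] >= w1 for w0, w1 in windows):
                    break
            else:
                raise ValueError(f"could not place non-overlapping sites in gene {g}")
            seq[span[0] : span[1]] = list(pattern)
            windows.append(span)
            planted_sites.append((g, m, pos, site_type))
        if clean:
            seq = _repair_background(seq, all_patterns, windows, rng)
        records.append(UTRRecord(gene=g, isoform="utr1", assembly="sim", sequence="".join(seq)))

    truth.planted_sites = sorted(set(truth.planted_sites) | set(planted_sites))
    return records, truth


def _repair_background(seq: np.ndarray, patterns: list[str], windows: list[tuple[int, int]], rng, max_iter: int = 20000):
    """Mutate single bases until no pattern occurs outside the planted windows."""
    alphabet = "ACGT"
    text = "".join(seq)
    for _ in range(max_iter):
        hit = None
        for p in patterns:
            i = text.find(p)
            while i != -1:
                if not any(w0 <= i and i + len(p) <= w1 for w0, w1 in windows):
                    hit = (i, i + len(p))
                    break
                i = text.find(p, i + 1)
            if hit:
                break
        if hit is None:
            return np.array(list(text))
        candidates = [j for j in range(*hit) if not any(w0 <= j < w1 for w0, w1 in windows)]
        if not candidates:
            raise RuntimeError("spurious site lies entirely inside a planted window; catalog not clean-compatible")
        j = candidates[int(rng.integers(len(candidates)))]
        old = text[j]
        new = alphabet[int(rng.integers(4))]
        while new == old:
            new = alphabet[int(rng.integers(4))]
        text = text[:j] + new + text[j + 1 :]
    raise RuntimeError("background repair did not converge")


def simulate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata: one row per sample (age, 0/1 sex, 0/1 MSI per subject)."""
    rng = config.rng("metadata")
    age = np.round(rng.normal(config.age_mean, config.age_sd, size=config.n_subjects), 1)
    sex = (rng.random(config.n_subjects) < config.male_prop).astype(int)  # 1 = male
    msi = (rng.random(config.n_subjects) < config.msi_prop).astype(int)
    normal_ids, tumor_ids = config.sample_ids()
    rows = []
    for i, subj in enumerate(config.subject_ids):
        for sample, tissue in ((normal_ids[i], "normal"), (tumor_ids[i], "carcinoma")):
            rows.append(
                {"sample_id": sample, "subject_id": subj, "tissue": tissue,
                 "age": age[i], "sex": int(sex[i]), "msi": int(msi[i])}
            )
    return pd.DataFrame(rows, columns=["sample_id", "subject_id", "tissue", "age", "sex", "msi"])
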