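"""Seeded multi-group count-study generator with planted signature effects.

The generator emulates a five-group chronic-pain stimulation study: a healthy
naive group, an untreated pain-model reference group, and several treatment
arms, with gene counts drawn from a negative-binomial model on top of
gene-wise lognormal baseline abundances and per-sample library sizes.

A configurable fraction of each signature's genes is perturbed by the pain
model (log2 effect of fixed magnitude, configurable up/down split). Each
treatment arm moves every perturbed gene back toward its baseline mean by a
per-gene recovery fraction drawn around the arm's configured recovery level
rho:

    r_g ~ Normal(rho, recovery_spread * (1 - rho))
    treatment log2 mean = pain mean - r_g * (pain mean - naive mean)

With ``recovery_spread = 0`` every perturbed gene recovers by exactly rho
(the homogeneous limit). The default spread of 1 models heterogeneous
per-gene responsiveness: weakly recovering programs leave many genes drifting
away from baseline while strongly recovering programs act consistently,
which is what makes threshold-based recovery shares discriminate treatment
arms the way profile correlations do. rho = 1 returns perturbed genes exactly
to the naive mean; rho > 1 models overshoot.

Every planted quantity is recorded in a TruthRecord so downstream estimates
can be checked against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .preprocess import CountStudy, Roles

__all__ = ["SignatureSpec", "SimConfig", "TruthRecord", "simulate_study", "write_study"]


@dataclass(frozen=True)
class SignatureSpec:
    """One planted literature-style signature.

    size:               number of symbols written to the signature list file.
    perturbed_fraction: fraction of the in-universe members changed by the
                        pain model.
    up_fraction:        fraction of perturbed members that go up.
    effect_log2fc:      magnitude of the planted pain effect (log2).
    """

    name: str
    size: int
    perturbed_fraction: float
    up_fraction: float
    effect_log2fc: float = 1.0

    def validate(self) -> None:
        if self.size <= 0:
            raise ConfigurationError(f"signature {self.name!r}: size must be positive")
        for f_name in ("perturbed_fraction", "up_fraction"):
            v = getattr(self, f_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(
                    f"signature {self.name!r}: {f_name} must be in [0,1], got {v}"
                )
        if self.effect_log2fc <= 0:
            raise ConfigurationError(
                f"signature {self.name!r}: effect_log2fc must be positive"
            )


def _default_signatures() -> tuple[SignatureSpec, ...]:
    # Sizes scaled to the default universe; perturbed/up fractions mirror the
    # disease-response levels of the three published microglial composites.
    return (
        SignatureSpec("resting", 500, 0.38, 0.49),
        SignatureSpec("post_injury", 1200, 0.33, 0.61),
        SignatureSpec("neuroprotective", 500, 0.58, 0.47),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic study.

    Defaults emulate the five-group stimulation study (naive n=7, untreated
    reference n=10, and three arms n=9/10/11) with graded recovery levels.
    """

    n_genes: int = 4000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"naive": 7, "no_scs": 10, "dtmp": 9, "hrp": 10, "lrp": 11}
    )
    naive_group: str = "naive"
    reference_group: str = "no_scs"
    treatment_recovery: dict[str, float] = field(
        default_factory=lambda: {"dtmp": 0.8, "hrp": 0.5, "lrp": 0.2}
    )
    recovery_spread: float = 1.0
    baseline_log2_mean_sd: tuple[float, float] = (7.0, 1.5)
    dispersion: float = 0.005
    signature_specs: tuple[SignatureSpec, ...] = field(default_factory=_default_signatures)
    library_size_range: tuple[int, int] = (1_500_000, 2_500_000)
    overlap_fraction: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not self.group_sizes:
            raise ConfigurationError("group_sizes must not be empty")
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ConfigurationError(f"group_sizes[{g!r}] must be positive, got {n}")
        for role, g in (("naive_group", self.naive_group), ("reference_group", self.reference_group)):
            if g not in self.group_sizes:
                raise ConfigurationError(f"{role} {g!r} is not a key of group_sizes")
        if self.naive_group == self.reference_group:
            raise ConfigurationError("naive_group and reference_group must differ")
        for t, rho in self.treatment_recovery.items():
            if t not in self.group_sizes:
                raise ConfigurationError(f"treatment {t!r} is not a key of group_sizes")
            if t in (self.naive_group, self.reference_group):
                raise ConfigurationError(f"treatment {t!r} clashes with a baseline role")
            if not 0.0 <= rho <= 1.5:
                raise ConfigurationError(
                    f"treatment_recovery[{t!r}] must be in [0, 1.5], got {rho}"
                )
        if self.recovery_spread < 0:
            raise ConfigurationError("recovery_spread must be >= 0")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ConfigurationError(
                f"overlap_fraction must be in (0,1], got {self.overlap_fraction}"
            )
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"library_size_range invalid: ({lo}, {hi})")
        names = [s.name for s in self.signature_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("signature names must be unique")
        for s in self.signature_specs:
            s.validate()
        in_universe = sum(int(s.size * self.overlap_fraction) for s in self.signature_specs)
        if in_universe > self.n_genes:
            raise ConfigurationError(
                f"signature_specs claim {in_universe} in-universe genes but n_genes={self.n_genes}"
            )

    @property
    def roles(self) -> Roles:
        return Roles(
            naive=self.naive_group,
            reference=self.reference_group,
            treatments=tuple(self.treatment_recovery),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["signature_specs"] = [dataclasses.asdict(s) for s in self.signature_specs]
        d["baseline_log2_mean_sd"] = list(self.baseline_log2_mean_sd)
        d["library_size_range"] = list(self.library_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown simulate config keys: {sorted(unknown)}")
        if "signature_specs" in d:
            d["signature_specs"] = tuple(
                s if isinstance(s, SignatureSpec) else SignatureSpec(**s)
                for s in d["signature_specs"]
            )
        for key in ("baseline_log2_mean_sd", "library_size_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth of a simulated study.

    genes: per-gene table (signature membership, perturbed flag, direction,
           planted pain log2FC, per-treatment applied recovery fraction).
    signature_symbols: the full symbol list written to each signature file,
           including the symbols deliberately absent from the universe.
    """

    genes: pd.DataFrame
    signature_symbols: dict[str, list[str]]
    config: SimConfig


def simulate_study(config: SimConfig) -> tuple[CountStudy, TruthRecord]:
    """Generate a seeded count study with planted effects.

    Identical configs (including seed) produce identical output. With all
    perturbed fractions at 0, all groups share the same expected mean for
    every gene; for a treatment with rho = 1 and zero spread, perturbed genes'
    treatment means equal their naive means exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]

    mean_l2, sd_l2 = config.baseline_log2_mean_sd
    mu = rng.normal(mean_l2, sd_l2, size=n)

    # Disjoint random signature blocks within the universe.
    order = rng.permutation(n)
    truth = pd.DataFrame(
        {
            "signature": pd.Series([""] * n, dtype=object),
            "perturbed": np.zeros(n, dtype=bool),
            "direction": np.zeros(n, dtype=int),
            "pain_log2fc": np.zeros(n, dtype=float),
        },
        index=gene_ids,
    )
    delta = np.zeros(n)
    signature_symbols: dict[str, list[str]] = {}
    pos = 0
    for spec in config.signature_specs:
        n_in = int(spec.size * config.overlap_fraction)
        block = order[pos : pos + n_in]
        pos += n_in
        n_pert = int(round(n_in * spec.perturbed_fraction))
        n_up = int(round(n_pert * spec.up_fraction))
        perturbed = block[:n_pert]
        signs = np.full(n_pert, -1, dtype=int)
        signs[:n_up] = 1
        signs = rng.permutation(signs)
        delta[perturbed] = signs * spec.effect_log2fc
        rows = truth.index[block]
        truth.loc[rows, "signature"] = spec.name
        p_rows = truth.index[perturbed]
        truth.loc[p_rows, "perturbed"] = True
        truth.loc[p_rows, "direction"] = signs
        truth.loc[p_rows, "pain_log2fc"] = signs * spec.effect_log2fc
        absent = [f"{spec.name.upper()}_ABSENT{k + 1:04d}" for k in range(spec.size - n_in)]
        symbols = [gene_ids[g] for g in block] + absent
        signature_symbols[spec.name] = [symbols[k] for k in rng.permutation(len(symbols))]

    # Per-group log2 means.
    group_mu: dict[str, np.ndarray] = {}
    for group in config.group_sizes:
        if group == config.naive_group:
            group_mu[group] = mu
        elif group == config.reference_group or group not in config.treatment_recovery:
            # untreated arms share the reference (pain) means
            group_mu[group] = mu + delta
        else:
            rho = config.treatment_recovery[group]
            r_g = rng.normal(rho, config.recovery_spread * (1.0 - rho), size=n)
            applied = np.where(truth["perturbed"].to_numpy(), r_g, np.nan)
            truth[f"recovery_{group}"] = applied
            group_mu[group] = mu + (1.0 - r_g) * delta

    # Sampling: per-sample library size, NB counts via gamma-Poisson mixture.
    lo, hi = config.library_size_range
    shape = 1.0 / config.dispersion
    columns: dict[str, np.ndarray] = {}
    design: dict[str, str] = {}
    for group, size in config.group_sizes.items():
        weights = np.power(2.0, group_mu[group])
        frac = weights / weights.sum()
        for i in range(size):
            sample = f"{group}_{i + 1:02d}"
            lib = int(rng.integers(lo, hi + 1))
            m = lib * frac
            lam = rng.gamma(shape, m / shape)
            columns[sample] = rng.poisson(lam)
            design[sample] = group
    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    study = CountStudy(counts, pd.Series(design), config.roles)
    return study, TruthRecord(genes=truth, signature_symbols=signature_symbols, config=config)


def write_study(study: CountStudy, truth: TruthRecord, out_dir) -> dict:
    """Write a simulated study to disk and return (and save) its manifest.

    Emits counts.tsv, design.tsv, one signature_<name>.txt per signature,
    truth.tsv and manifest.yaml (recording the seed and full config so reruns
    are reproducible).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    counts_path = out / "counts.tsv"
    study.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    files["counts"] = counts_path.name

    design_path = out / "design.tsv"
    study.design.rename_axis("sample_id").rename("group").to_csv(design_path, sep="\t")
    files["design"] = design_path.name

    for name, symbols in truth.signature_symbols.items():
        p = out / f"signature_{name}.txt"
        p.write_text("\n".join(symbols) + "\n")
        files[f"signature_{name}"] = p.name

    truth_path = out / "truth.tsv"
    truth.genes.rename_axis("gene_id").to_csv(truth_path, sep="\t")
    files["truth"] = truth_path.name

    manifest = {
        "seed": truth.config.seed,
        "n_genes": truth.config.n_genes,
        "files": files,
        "config": truth.config.to_dict(),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
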