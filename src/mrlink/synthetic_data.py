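"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of a thyroid-function-style MR study:
an exposure GWAS of J independent instruments and one or more outcome
GWASs over the same variants, under the linear causal model

    beta_x_j ~ Normal(gamma_j, se_x_j^2)
    beta_y_j ~ Normal(causal_beta * gamma_j + alpha_j, se_y_j^2)

where ``gamma_j`` is the true instrument strength and ``alpha_j`` a direct
(horizontally pleiotropic) effect on the outcome — zero for valid
instruments, drawn ``Normal(pleiotropy_mean, pleiotropy_sd^2)`` for the
configured invalid fraction (mean 0 under balanced pleiotropy).  P-values
follow the normal approximation.  Allele pairs follow a
transition-biased substitution spectrum, making roughly one in six
variants palindromic (A/T or C/G); outcome records are randomly re-oriented
(allele order swapped, strand complemented) so harmonization is always
exercised.  Effect-allele frequencies are kept at least 0.10 away from
0.5 so palindromic variants remain resolvable by frequency.

Defaults are stylized for a GWAS of roughly 70k individuals: instrument
strengths ``Normal(0.02, 0.01)`` SD per allele with ``se_x = 0.003``.

A single master seed fans out to per-dataset seeds through
``numpy.random.SeedSequence`` with a fixed counter scheme, so adding
datasets to a panel never perturbs existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_summary import COMPLEMENT, SummaryRecord

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "generate_dataset",
    "generate_outcome",
    "generate_thyroid_panel",
    "write_summary_table",
]

ALLELES = "ACGT"
# transition-biased substitution spectrum: A<->G and C<->T each 1/3, the
# four transversion pairs 1/12 each, so ~1/6 of variants are palindromic
_PAIR_TYPES = [("A", "G"), ("C", "T"), ("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]
_PAIR_WEIGHTS = np.array([4, 4, 1, 1, 1, 1]) / 12.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated exposure/outcome dataset.

    ``invalid_fraction * n_snp`` is rounded to the count of invalid
    (pleiotropic) instruments.  ``se_x`` and ``se_y`` may be scalars or
    per-variant arrays.  ``ensure_significant`` redraws observed exposure
    betas until each variant passes genome-wide significance — used for
    panels whose instrument counts are fixed by construction.
    """

    n_snp: int
    causal_beta: float = 0.0
    exposure_scale: str = "per_sd"
    beta_x_mean: float = 0.02
    beta_x_sd: float = 0.01
    se_x: float | Sequence[float] = 0.003
    se_y: float | Sequence[float] = 0.01
    invalid_fraction: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    ld_block_spec: tuple[tuple[int, float], ...] | None = None
    seed: int = 0
    ensure_significant: bool = False
    p_threshold: float = 5e-8
    id_prefix: str | None = None  # default "rs<seed mod 1000>"

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must be in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode == "none" and (self.pleiotropy_sd or self.pleiotropy_mean):
            raise ValueError("pleiotropy_mode 'none' requires zero sd and mean")
        if self.pleiotropy_mode == "balanced" and self.pleiotropy_mean != 0:
            raise ValueError("balanced pleiotropy requires pleiotropy_mean = 0")

    @property
    def n_invalid(self) -> int:
        return int(round(self.invalid_fraction * self.n_snp))


@dataclass
class SimulatedDataset:
    """Exposure and outcome records plus the latent truth that made them."""

    exposure: list[SummaryRecord]
    outcome: list[SummaryRecord]
    truth: dict
    ld_table: dict | None = None


def _child_rng(master_seed: int, *counters: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, counters)]))


def _draw_eaf(rng: np.random.Generator, n: int) -> np.ndarray:
    # at least 0.10 from 0.5: palindromic variants stay frequency-resolvable
    eaf = rng.uniform(0.05, 0.40, size=n)
    flip = rng.random(n) < 0.5
    return np.where(flip, 1.0 - eaf, eaf)


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Draw one exposure GWAS and one matching outcome GWAS.

    Returns records in the same shape :mod:`mrlink.gwas_summary` reads,
    plus a truth record carrying every latent (instrument strengths,
    direct effects, validity mask, observed values and the config).
    """
    rng = _child_rng(config.seed, 0)
    n = config.n_snp
    se_x = np.broadcast_to(np.asarray(config.se_x, dtype=float), (n,)).copy()
    se_y = np.broadcast_to(np.asarray(config.se_y, dtype=float), (n,)).copy()

    gamma = rng.normal(config.beta_x_mean, config.beta_x_sd, size=n)
    alpha = np.zeros(n)
    n_invalid = config.n_invalid
    invalid = np.zeros(n, dtype=bool)
    if n_invalid and config.pleiotropy_mode != "none":
        invalid[rng.choice(n, size=n_invalid, replace=False)] = True
        alpha[invalid] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd,
                                    size=n_invalid)

    bx = rng.normal(gamma, se_x)
    if config.ensure_significant:
        # rejection-sample observed exposure betas until genome-wide significant
        for _ in range(10_000):
            p = 2 * stats.norm.sf(np.abs(bx) / se_x)
            bad = p >= config.p_threshold
            if not bad.any():
                break
            gamma[bad] = rng.normal(
                np.maximum(np.abs(config.beta_x_mean), 8 * se_x[bad]),
                config.beta_x_sd, size=int(bad.sum()))
            bx[bad] = rng.normal(gamma[bad], se_x[bad])
    by = rng.normal(config.causal_beta * gamma + alpha, se_y)

    eaf = _draw_eaf(rng, n)
    pair_idx = rng.choice(len(_PAIR_TYPES), size=n, p=_PAIR_WEIGHTS)
    pair_swap = rng.random(n) < 0.5
    prefix = config.id_prefix or f"rs{config.seed % 1000}"
    ids = [f"{prefix}{j:05d}" for j in range(n)]

    p_x = np.clip(2 * stats.norm.sf(np.abs(bx) / se_x), 1e-320, 1.0)
    p_y = np.clip(2 * stats.norm.sf(np.abs(by) / se_y), 1e-320, 1.0)

    exposure, outcome = [], []
    for j in range(n):
        ea, oa = _PAIR_TYPES[pair_idx[j]]
        if pair_swap[j]:
            ea, oa = oa, ea
        exposure.append(SummaryRecord(ids[j], ea, oa, float(eaf[j]),
                                      float(bx[j]), float(se_x[j]), float(p_x[j])))
        outcome.append(_reorient(rng, ids[j], ea, oa, float(eaf[j]),
                                 float(by[j]), float(se_y[j]), float(p_y[j])))

    ld_table = None
    if config.ld_block_spec:
        ld_table = {}
        start = 0
        for size, r2 in config.ld_block_spec:
            block = ids[start:start + size]
            for a in range(len(block)):
                for b in range(a + 1, len(block)):
                    ld_table[frozenset((block[a], block[b]))] = float(r2)
            start += size

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "variant_ids": ids,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "invalid": invalid.tolist(),
        "beta_x_obs": bx.tolist(),
        "beta_y_obs": by.tolist(),
        "causal_beta": config.causal_beta,
    }
    return SimulatedDataset(exposure, outcome, truth, ld_table)


def _reorient(rng, vid, ea, oa, eaf, beta, se, p) -> SummaryRecord:
    """Randomly swap allele order and/or strand for an outcome record.

    Both transformations are recoverable by harmonization: an allele-order
    swap negates the beta and mirrors the frequency; a strand complement
    changes labels only (palindromic variants are never strand-flipped
    here since the flip would be a no-op on the label pair anyway)."""
    if rng.random() < 0.5:
        ea, oa, beta, eaf = oa, ea, -beta, 1.0 - eaf
    if {ea, oa} not in ({"A", "T"}, {"C", "G"}) and rng.random() < 0.5:
        ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
    return SummaryRecord(vid, ea, oa, eaf, beta, se, p)


def generate_outcome(
    dataset: SimulatedDataset, seed: int, causal_beta: float | None = None,
    se_y: float | Sequence[float] | None = None,
) -> list[SummaryRecord]:
    """Draw an additional outcome cohort from a dataset's latent truth.

    Reuses the instrument strengths and direct effects, with fresh outcome
    sampling noise — the second cohort of a meta-analysis.
    """
    rng = _child_rng(seed, 1)
    t = dataset.truth
    n = len(t["variant_ids"])
    gamma = np.asarray(t["gamma"])
    alpha = np.asarray(t["alpha"])
    cb = t["causal_beta"] if causal_beta is None else causal_beta
    if se_y is None:
        se_y = [r.se for r in dataset.outcome]
    se_y = np.broadcast_to(np.asarray(se_y, dtype=float), (n,)).copy()
    by = rng.normal(cb * gamma + alpha, se_y)
    p_y = np.clip(2 * stats.norm.sf(np.abs(by) / se_y), 1e-320, 1.0)
    out = []
    for j, rec in enumerate(dataset.exposure):
        out.append(_reorient(rng, rec.variant_id, rec.effect_allele,
                             rec.other_allele, rec.eaf,
                             float(by[j]), float(se_y[j]), float(p_y[j])))
    return out


def write_summary_table(records: Sequence[SummaryRecord], path) -> None:
    """Write records in the delimited format :func:`read_summary_table` reads."""
    df = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pvalue": [r.pvalue for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# instrument counts of the four thyroid-function exposures; the TSH set
# includes one designated pleiotropic-locus variant for exclusion testing
PANEL_EXPOSURES = (
    ("tsh", 61, "per_sd", -0.06, True),
    ("hypothyroidism", 8, "per_logodds", -0.02, False),
    ("hyperthyroidism", 8, "per_logodds", 0.02, False),
    ("free_thyroxine", 31, "per_sd", 0.05, False),
)


def generate_thyroid_panel(seed: int, out_dir=None) -> dict:
    """Generate the four-exposure thyroid-style panel with two outcome cohorts.

    Emits, per exposure: an exposure summary table, two outcome cohorts
    (``cohort_a`` with every variant present; ``cohort_b`` missing a few
    variants, with a proxy table covering some of them), an exclusion list
    for the TSH-like exposure (one pleiotropic-locus variant), and a truth
    file.  When ``out_dir`` is given everything is also written as TSV /
    JSON under one directory per exposure.
    """
    panel: dict = {"seed": int(seed), "exposures": {}}
    for k, (name, n_snp, scale, causal, with_exclusion) in enumerate(PANEL_EXPOSURES):
        child = int(np.random.SeedSequence([int(seed), 100 + k]).generate_state(1)[0] % (2**31))
        strong = scale == "per_logodds"
        cfg = SimConfig(
            n_snp=n_snp, causal_beta=causal, exposure_scale=scale,
            beta_x_mean=0.15 if strong else 0.03,
            beta_x_sd=0.05 if strong else 0.008,
            se_x=0.02 if strong else 0.003,
            se_y=0.02, seed=child, ensure_significant=True,
            id_prefix=f"rs_{name}_",
        )
        ds = generate_dataset(cfg)
        cohort_b = generate_outcome(ds, seed=child + 1)

        rng = _child_rng(child, 2)
        ids = [r.variant_id for r in ds.exposure]
        exclusion = [ids[int(rng.integers(n_snp))]] if with_exclusion else []

        # cohort_b misses a few instruments; proxies exist for some of them
        n_missing = min(3, n_snp - 2) if n_snp > 10 else 1
        missing = list(rng.choice(ids, size=n_missing, replace=False))
        present_b = [r for r in cohort_b if r.variant_id not in set(missing)]
        proxy_rows = []
        for m, vid in enumerate(missing[:max(1, n_missing - 1)]):
            src = next(r for r in cohort_b if r.variant_id == vid)
            sign = int(rng.choice([1, -1]))
            pid = f"{vid}_proxy"
            proxy_rows.append((vid, pid, float(rng.uniform(0.92, 0.99)), sign))
            # the proxy's outcome association mirrors the target's up to sign
            present_b.append(SummaryRecord(
                pid, src.effect_allele, src.other_allele, src.eaf,
                sign * src.beta, src.se, src.pvalue))

        entry = {
            "name": name,
            "scale": scale,
            "exposure": ds.exposure,
            "cohort_a": ds.outcome,
            "cohort_b": present_b,
            "exclusion": exclusion,
            "proxy_table": {t: [(p, r2, s)] for t, p, r2, s in proxy_rows},
            "truth": ds.truth,
        }
        panel["exposures"][name] = entry

        if out_dir is not None:
            d = Path(out_dir) / name
            d.mkdir(parents=True, exist_ok=True)
            write_summary_table(ds.exposure, d / "exposure.tsv")
            write_summary_table(ds.outcome, d / "outcome_cohort_a.tsv")
            write_summary_table(present_b, d / "outcome_cohort_b.tsv")
            (d / "exclusion.txt").write_text("".join(f"{v}\n" for v in exclusion))
            pd.DataFrame(proxy_rows,
                         columns=["target_id", "proxy_id", "r2", "sign"]
                         ).to_csv(d / "proxies.tsv", sep="\t", index=False)
            (d / "truth.json").write_text(json.dumps(ds.truth, indent=1))
    return panel
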