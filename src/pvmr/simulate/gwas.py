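"""Seeded generator of paired exposure/outcome GWAS summary statistics.

Simulates the two-sample MR setting at the summary-statistic level (no
individual genotypes): per-SNP exposure associations drawn on the
plasma-protein scale of a small proteomic GWAS, outcome associations
generated from the linear model

    beta_out_j = beta_causal * beta_exp_j + pleiotropy_j + het_j + noise_j

with configurable balanced or directional pleiotropy, extra heterogeneity,
and sampling noise at the outcome GWAS's standard-error scale.  Default
sample sizes (3,301 exposure; 178,726 outcome) and exposure effect / SE
scales mirror a small protein-level exposure study instrumented against a
large biobank outcome.  A truth record captures every latent quantity so
any generated value can be recomputed from the seed.

``simulate_ld_panel`` builds a block-structured r-squared lookup with
positions placed inside or outside the clumping window, for exercising
instrument selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ..mr import LdMatrix, SnpAssociation

_NON_PALINDROMIC = [("A", "G"), ("A", "C"), ("T", "C"), ("T", "G"),
                    ("G", "A"), ("C", "A"), ("C", "T"), ("G", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(slots=True)
class GwasSimConfig:
    """Study conditions for one simulated exposure/outcome pair."""

    k_snps: int = 9
    beta_causal: float = 0.0
    exposure_beta_range: tuple[float, float] = (0.1, 0.5)
    se_exp: float = 0.05
    se_out: float = 0.14
    n_exp: int = 3301
    n_out: int = 178_726
    pleiotropy: str = "none"          # none | balanced | directional
    pleiotropy_mean: float = 0.0      # directional only
    pleiotropy_sd: float = 0.0
    heterogeneity_sd: float = 0.0
    palindromic_frac: float = 0.0
    palindromic_eaf_range: tuple[float, float] = (0.44, 0.56)
    ld_blocks: Sequence[int] | None = None
    ld_within_r2: float = 0.9
    ld_block_spacing_kb: float = 20_000
    seed: int = 0

    def validate(self) -> None:
        if self.k_snps < 1:
            raise ValueError("k_snps must be >= 1")
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError("se scales must be > 0")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy must be none|balanced|directional")
        if min(self.pleiotropy_sd, self.heterogeneity_sd) < 0:
            raise ValueError("sds must be >= 0")
        if not 0.0 <= self.palindromic_frac <= 1.0:
            raise ValueError("palindromic_frac must be in [0, 1]")


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def simulate_gwas_pair(
    c: GwasSimConfig,
) -> tuple[list[SnpAssociation], list[SnpAssociation], dict]:
    """Draw one exposure panel, its outcome panel and the truth record.

    Exposure effect sizes are uniform over ``exposure_beta_range``
    (positive, per-allele); outcome effects follow the configured linear
    model.  A random subset of outcome rows is reported on the swapped
    allele orientation (with the beta sign flipped accordingly) so that
    harmonization has real work to do; the truth record lists which.
    """
    c.validate()
    rng = np.random.default_rng(c.seed)
    k = c.k_snps

    beta_exp = rng.uniform(*c.exposure_beta_range, k)
    pleio = np.zeros(k)
    if c.pleiotropy == "balanced":
        pleio = rng.normal(0.0, c.pleiotropy_sd, k)
    elif c.pleiotropy == "directional":
        pleio = rng.normal(c.pleiotropy_mean, c.pleiotropy_sd, k)
    het = rng.normal(0.0, c.heterogeneity_sd, k) if c.heterogeneity_sd > 0 else np.zeros(k)
    noise = rng.normal(0.0, c.se_out, k)
    beta_out = c.beta_causal * beta_exp + pleio + het + noise

    se_exp = np.full(k, c.se_exp)
    se_out = np.full(k, c.se_out)
    p_exp = _two_sided_p(beta_exp, se_exp)
    p_out = _two_sided_p(beta_out, se_out)

    palindromic = rng.random(k) < c.palindromic_frac
    alleles = []
    eaf = np.empty(k)
    for j in range(k):
        if palindromic[j]:
            alleles.append(_PALINDROMIC[rng.integers(len(_PALINDROMIC))])
            eaf[j] = rng.uniform(*c.palindromic_eaf_range)
        else:
            alleles.append(_NON_PALINDROMIC[rng.integers(len(_NON_PALINDROMIC))])
            eaf[j] = rng.uniform(0.05, 0.95)

    chroms = [str(1 + j % 22) for j in range(k)]
    positions = [1_000_000 + 25_000_000 * (j // 22) for j in range(k)]
    swap = rng.random(k) < 0.5  # outcome reported on the swapped orientation

    exposure, outcome = [], []
    for j in range(k):
        ea, oa = alleles[j]
        sid = f"rs{100000 + j}"
        exposure.append(
            SnpAssociation(sid, chroms[j], positions[j], ea, oa, float(eaf[j]),
                           float(beta_exp[j]), float(se_exp[j]), float(p_exp[j]), c.n_exp)
        )
        if swap[j] and not palindromic[j]:
            o_ea, o_oa, o_beta, o_eaf = oa, ea, -beta_out[j], 1 - eaf[j]
        else:
            o_ea, o_oa, o_beta, o_eaf = ea, oa, beta_out[j], eaf[j]
        outcome.append(
            SnpAssociation(sid, chroms[j], positions[j], o_ea, o_oa, float(o_eaf),
                           float(o_beta), float(se_out[j]), float(p_out[j]), c.n_out)
        )

    truth = {
        "seed": c.seed,
        "beta_causal": c.beta_causal,
        "beta_exp": beta_exp.tolist(),
        "beta_out": beta_out.tolist(),
        "pleiotropy": pleio.tolist(),
        "heterogeneity": het.tolist(),
        "noise_out": noise.tolist(),
        "palindromic": palindromic.tolist(),
        "outcome_swapped": swap.tolist(),
        "se_exp": c.se_exp,
        "se_out": c.se_out,
    }
    return exposure, outcome, truth


@dataclass(frozen=True, slots=True)
class LdPanel:
    ld: LdMatrix
    snp_ids: list[str]
    chrom: list[str]
    pos: list[int]


def simulate_ld_panel(c: GwasSimConfig) -> LdPanel:
    """Block-structured LD: within-block r2 at ``ld_within_r2``, zero
    between blocks; block spacing controls whether neighbouring blocks fall
    inside the clumping window."""
    if not c.ld_blocks:
        raise ValueError("ld_blocks must be set")
    ld = LdMatrix()
    ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    cursor = 1_000_000
    for b, size in enumerate(c.ld_blocks):
        members = []
        for j in range(size):
            sid = f"rs{200000 + len(ids)}"
            ids.append(sid)
            chrom.append("1")
            pos.append(cursor)
            members.append(sid)
            cursor += 1000  # 1 kb apart within a block
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ld.set(members[i], members[j], c.ld_within_r2)
        cursor += int(c.ld_block_spacing_kb * 1000)
    return LdPanel(ld, ids, chrom, pos)
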