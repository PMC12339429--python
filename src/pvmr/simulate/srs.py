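"""Seeded generator of spontaneous-report datasets with a planted signal.

Each simulated report independently lists the target drug with probability
``p_drug`` and the target adverse-event PT with probability
``p_event_background`` (multiplied by the planted relative risk ``rr`` when
the drug is present, optionally shifted on the logit scale by a per-age-band
effect).  Decoy PTs are independent Bernoulli noise, demographics are drawn
from configurable marginals patterned on a FAERS-like case mix, and an
optional duplicate-injection mode exercises deduplication.  Everything is
reproducible from the seed.

For rare events the expected reporting odds ratio of the target pair
approximates the planted ``rr``, which is what the disproportionality stage
assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from ..reports import ReportRecord, ReportSet

TARGET_DRUG = "somatropin"
TARGET_PT = (10061019, "brain neoplasm")

#: FAERS-like default demographic marginals
DEFAULT_DEMOGRAPHICS = {
    # probability of an age draw per descriptive band; remainder is missing
    "age_bands": {
        (0, 12): 0.099, (12, 18): 0.131, (18, 35): 0.057,
        (35, 65): 0.223, (65, 80): 0.033, (80, 100): 0.007,
    },
    "sex": {"female": 0.482, "male": 0.468, "unknown": 0.050},
    "outcome": {
        "death": 0.021, "disability": 0.007, "hospitalization": 0.170,
        "life_threatening": 0.021, "unknown": 0.053, "other": 0.728,
    },
    "country": {
        "US": 0.255, "GB": 0.252, "CA": 0.149, "CO": 0.046, "TR": 0.039,
        "other": 0.259,
    },
}

DECOY_DRUGS = ("ibuprofen", "metformin", "lisinopril", "omeprazole", "sertraline")


@dataclass(slots=True)
class SrsConfig:
    """Study conditions for one simulated spontaneous-report dataset.

    Defaults plant a rare-event regime: 200k reports, 0.5% of reports
    listing the target drug, a 0.03% background PT rate and a relative risk
    of 12 for the PT given the drug, which puts the expected ROR near the
    strong-signal scale seen in real growth-hormone/brain-neoplasm mining.
    """

    n_reports: int = 200_000
    p_drug: float = 0.005
    p_event_background: float = 0.0003
    rr: float = 12.0
    n_decoy_pts: int = 20
    decoy_rate_range: tuple[float, float] = (1e-4, 1e-2)
    demographics: dict = field(default_factory=lambda: DEFAULT_DEMOGRAPHICS)
    age_effect: dict[str, float] | None = None  # regression band -> log-OR
    duplicate_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        probs = [self.p_drug, self.p_event_background, self.duplicate_rate]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.rr <= 0:
            raise ValueError("rr must be > 0")
        if self.p_event_background * self.rr > 1.0:
            raise ValueError("p_event_background * rr exceeds 1")
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")


def _logit_shift(p: np.ndarray, shift: np.ndarray) -> np.ndarray:
    logit = np.log(p / (1 - p)) + shift
    return 1.0 / (1.0 + np.exp(-logit))


def _sample_categorical(rng: np.random.Generator, table: dict, n: int) -> np.ndarray:
    keys = list(table)
    p = np.array([table[k] for k in keys], float)
    p = p / p.sum()
    return rng.choice(len(keys), size=n, p=p), keys


def simulate_srs(c: SrsConfig) -> ReportSet:
    """Draw one ReportSet under the configured planted-signal model."""
    from ..reports import assign_age_band  # local to avoid cycle

    c.validate()
    rng = np.random.default_rng(c.seed)
    n = c.n_reports

    drug = rng.random(n) < c.p_drug

    # ages: draw a band (or missing), then a uniform age within the band
    demo = c.demographics
    band_items = list(demo["age_bands"].items())
    p_bands = np.array([p for _, p in band_items])
    p_missing = max(0.0, 1.0 - p_bands.sum())
    choice = rng.choice(len(band_items) + 1, size=n,
                        p=np.append(p_bands, p_missing))
    ages = np.full(n, np.nan)
    u = rng.random(n)
    for i, ((lo, hi), _) in enumerate(band_items):
        mask = choice == i
        ages[mask] = lo + u[mask] * (hi - lo)

    p_event = np.where(drug, c.p_event_background * c.rr, c.p_event_background)
    if c.age_effect:
        shift = np.zeros(n)
        for j in range(n):
            if not math.isnan(ages[j]):
                band = assign_age_band(float(ages[j]), "regression")
                shift[j] = c.age_effect.get(band, 0.0)
        p_event = _logit_shift(p_event, shift)
    event = rng.random(n) < p_event

    lo, hi = c.decoy_rate_range
    decoy_rates = np.exp(rng.uniform(math.log(lo), math.log(hi), c.n_decoy_pts))
    decoys = rng.random((n, c.n_decoy_pts)) < decoy_rates[None, :]

    sex_idx, sex_keys = _sample_categorical(rng, demo["sex"], n)
    out_idx, out_keys = _sample_categorical(rng, demo["outcome"], n)
    cty_idx, cty_keys = _sample_categorical(rng, demo["country"], n)
    bg_drug_idx = rng.integers(0, len(DECOY_DRUGS), n)
    day_offsets = rng.integers(0, 7300, n)  # receipt dates over ~20 years
    base_date = date(2005, 1, 1)

    decoy_pts = [(10000001 + j, f"decoy event {j + 1}") for j in range(c.n_decoy_pts)]
    # guarantee a nonempty PT set: a filler PT for reports with no event at all
    filler_pts = frozenset({(10000000, "drug ineffective")})
    target_only_pts = frozenset({TARGET_PT})

    # precompute immutable parts shared across records (the loop dominates
    # runtime for simulation studies)
    drug_sets = [frozenset({d}) for d in DECOY_DRUGS]
    drug_sets_t = [frozenset({d, TARGET_DRUG}) for d in DECOY_DRUGS]
    outcome_sets = [frozenset({k}) for k in out_keys]
    dates = [base_date + timedelta(days=k) for k in range(7300)]
    has_decoy = decoys.any(axis=1)
    age_list = [None if math.isnan(a) else round(float(a), 1) for a in ages]

    records: list[ReportRecord] = []
    for i in range(n):
        if has_decoy[i]:
            pts = {decoy_pts[j] for j in np.flatnonzero(decoys[i])}
            if event[i]:
                pts.add(TARGET_PT)
            pts = frozenset(pts)
        else:
            pts = target_only_pts if event[i] else filler_pts
        records.append(
            ReportRecord(
                report_id=f"R{i:08d}",
                case_version=0,
                drugs=(drug_sets_t if drug[i] else drug_sets)[bg_drug_idx[i]],
                pts=pts,
                age_years=age_list[i],
                sex=sex_keys[sex_idx[i]],
                country=cty_keys[cty_idx[i]],
                outcome=outcome_sets[out_idx[i]],
                receipt_date=dates[day_offsets[i]],
            )
        )

    n_dupes = int(round(c.duplicate_rate * n))
    if n_dupes:
        dupe_idx = rng.choice(n, size=n_dupes, replace=False)
        for i in dupe_idx:
            records.append(records[int(i)])

    counts = {"n_reports": n, "n_duplicates_injected": n_dupes,
              "n_target_drug": int(drug.sum()), "n_target_event": int(event.sum())}
    return ReportSet(records, provenance="synthetic-srs", counts=counts)
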