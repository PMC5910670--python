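"""Synthetic screens and in vivo time courses with planted ground truth.

The generators emulate the statistical structure the downstream analyses
assume:

* :func:`gen_screen` — an in vitro silencing screen.  The natural log of the
  fraction of target mRNA remaining is additive in a dose-level baseline, a
  planted per-position chemistry effect (2'-F relative to the 2'-OMe
  reference), a per-site and per-target offset, and Normal noise; on the
  fraction scale the noise is multiplicative lognormal, so observations stay
  strictly positive.  Defaults reproduce the screen geometry of the original
  study: 5 targets x 3 sites x 126 duplexes = 1,890 duplexes, transfected at
  10 and 0.1 nM in quadruplicate.
* :func:`gen_qpcr_plate` — raw qPCR Ct values (target + housekeeping,
  treated + control) consistent with a chosen knockdown under ddCt
  processing.
* :func:`gen_pkpd_timecourse` — an in vivo knockdown curve with
  onset/nadir/recovery, K(t) = kd_max*(1-exp(-k_on*t))*exp(-k_off*t), plus
  Ago2-loaded strand levels tied to knockdown by a planted semilog law
  100*K(t) = a + b*log10(L(t)).

Every generator is deterministic given its ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .strands import ANTISENSE_LENGTH, SENSE_LENGTH

__all__ = [
    "ScreenSimConfig",
    "QPCRSimConfig",
    "PKPDSimConfig",
    "default_gamma_sense",
    "default_gamma_antisense",
    "CRITICAL_POSITIONS",
    "gen_screen",
    "gen_qpcr_plate",
    "gen_pkpd_timecourse",
    "gen_dv_records",
    "parent_pkpd_config",
    "dv18_pkpd_config",
]

#: positions planted with the strongest 2'-F preference, mirroring the
#: critical positions identified in the original screen
CRITICAL_POSITIONS = (("AS", 2), ("AS", 6), ("AS", 14), ("S", 11))


def default_gamma_sense() -> np.ndarray:
    """Planted sense-strand positional effects (ln fraction-remaining scale).

    Negative = 2'-F improves silencing at that position.  S11 is the planted
    critical sense position; a few flanking positions carry mild effects and
    the rest are exact nulls.
    """
    g = np.zeros(SENSE_LENGTH)
    g[11 - 1] = -0.40  # S11: strong 2'-F preference
    g[6 - 1] = -0.15
    g[1 - 1] = +0.10
    g[16 - 1] = +0.08
    return g


def default_gamma_antisense() -> np.ndarray:
    """Planted antisense-strand positional effects (ln scale).

    AS2/AS6/AS14 are the planted critical 2'-F positions; AS8 is planted
    mildly harmful for 2'-F and AS9 mildly beneficial, echoing the opposed
    pair seen in the original model.
    """
    g = np.zeros(ANTISENSE_LENGTH)
    g[2 - 1] = -0.40
    g[6 - 1] = -0.35
    g[14 - 1] = -0.45
    g[8 - 1] = +0.20
    g[9 - 1] = -0.20
    g[16 - 1] = -0.10
    return g


@dataclass
class ScreenSimConfig:
    """Conditions for one synthetic in vitro screen.

    Defaults give 5 targets x 3 sites/target x 126 duplexes/site = 1,890
    duplexes, two transfection doses (10 and 0.1 nM), quadruplicate wells,
    and lognormal noise with sd 0.3 on the ln scale.
    """

    n_targets: int = 5
    sites_per_target: int = 3
    duplexes_per_site: int = 126
    doses_nM: Sequence[float] = (10.0, 0.1)
    replicates: int = 4
    gamma_sense: Optional[np.ndarray] = None
    gamma_antisense: Optional[np.ndarray] = None
    #: dose-level baseline of ln(fraction remaining); the higher dose
    #: silences more
    baseline_ln: Optional[dict] = None
    site_sd: float = 0.30
    target_sd: float = 0.20
    species_labels: Sequence[str] = ("mouse", "human")
    noise_sd: float = 0.30
    #: optional explicit list of (sense_chem_string, antisense_chem_string)
    #: pairs; otherwise patterns are drawn uniformly at random
    patterns: Optional[Sequence[tuple]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_targets <= 0 or self.sites_per_target <= 0 or self.duplexes_per_site <= 0:
            raise ValueError("all screen counts must be positive")
        if self.replicates <= 0:
            raise ValueError("replicates must be positive")
        if len(tuple(self.doses_nM)) == 0:
            raise ValueError("doses_nM must be non-empty")
        if self.noise_sd < 0 or self.site_sd < 0 or self.target_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.gamma_sense is None:
            self.gamma_sense = default_gamma_sense()
        self.gamma_sense = np.asarray(self.gamma_sense, dtype=float)
        if self.gamma_sense.shape != (SENSE_LENGTH,):
            raise ValueError(f"gamma_sense must have shape ({SENSE_LENGTH},)")
        if self.gamma_antisense is None:
            self.gamma_antisense = default_gamma_antisense()
        self.gamma_antisense = np.asarray(self.gamma_antisense, dtype=float)
        if self.gamma_antisense.shape != (ANTISENSE_LENGTH,):
            raise ValueError(f"gamma_antisense must have shape ({ANTISENSE_LENGTH},)")
        if self.baseline_ln is None:
            # ~80% knockdown at 10 nM, ~45% at 0.1 nM for a null-chemistry duplex
            self.baseline_ln = {10.0: -1.6, 0.1: -0.6}
        for d in self.doses_nM:
            if float(d) not in {float(k) for k in self.baseline_ln}:
                raise ValueError(f"baseline_ln missing an entry for dose {d} nM")

    @property
    def n_duplexes(self) -> int:
        return self.n_targets * self.sites_per_target * self.duplexes_per_site


def _encode(bits: np.ndarray) -> list:
    """0/1 matrix -> compact chemistry strings (1 = F, 0 = OMe -> 'M')."""
    lut = np.array(["M", "F"])
    return ["".join(row) for row in lut[bits]]


def gen_screen(config: ScreenSimConfig) -> pd.DataFrame:
    """Generate one synthetic screen as a tidy table of silencing records.

    Returns a DataFrame with columns ``duplex_id, target, site_id, species,
    dose_nM, replicate, sense_pattern, antisense_pattern,
    fraction_remaining``.  ``*_pattern`` columns are compact ``F``/``M``
    chemistry strings.  Identical config (including seed) yields an
    identical table.
    """
    rng = np.random.default_rng(config.seed)
    nT, nS, nD = config.n_targets, config.sites_per_target, config.duplexes_per_site
    n_dup = config.n_duplexes

    target_ids = [f"T{t + 1}" for t in range(nT)]
    site_ids = [f"T{t + 1}_S{s + 1}" for t in range(nT) for s in range(nS)]
    target_eff = rng.normal(0.0, config.target_sd, size=nT)
    site_eff = rng.normal(0.0, config.site_sd, size=nT * nS)
    # each target site lives in one cell line; species is a site attribute
    species = rng.choice(list(config.species_labels), size=nT * nS)

    if config.patterns is not None:
        pats = list(config.patterns)
        if len(pats) < n_dup:
            raise ValueError(f"need {n_dup} patterns, got {len(pats)}")
        sense_bits = np.array(
            [[1 if c == "F" else 0 for c in s] for s, _ in pats[:n_dup]], dtype=np.int8
        )
        anti_bits = np.array(
            [[1 if c == "F" else 0 for c in a] for _, a in pats[:n_dup]], dtype=np.int8
        )
    else:
        sense_bits = rng.integers(0, 2, size=(n_dup, SENSE_LENGTH), dtype=np.int8)
        anti_bits = rng.integers(0, 2, size=(n_dup, ANTISENSE_LENGTH), dtype=np.int8)

    chem_effect = sense_bits @ config.gamma_sense + anti_bits @ config.gamma_antisense

    # duplex-level frame
    site_index = np.repeat(np.arange(nT * nS), nD)
    target_index = site_index // nS
    duplex_ids = [
        f"{site_ids[si]}_D{d + 1:03d}" for si in range(nT * nS) for d in range(nD)
    ]
    mu_dup = chem_effect + site_eff[site_index] + target_eff[target_index]

    doses = [float(d) for d in config.doses_nM]
    baseline = {float(k): v for k, v in config.baseline_ln.items()}
    frames = []
    sense_strings = _encode(sense_bits)
    anti_strings = _encode(anti_bits)
    for dose in doses:
        for rep in range(1, config.replicates + 1):
            eps = rng.normal(0.0, config.noise_sd, size=n_dup)
            ln_frac = baseline[dose] + mu_dup + eps
            frames.append(
                pd.DataFrame(
                    {
                        "duplex_id": duplex_ids,
                        "target": [target_ids[t] for t in target_index],
                        "site_id": [site_ids[s] for s in site_index],
                        "species": [species[s] for s in site_index],
                        "dose_nM": dose,
                        "replicate": rep,
                        "sense_pattern": sense_strings,
                        "antisense_pattern": anti_strings,
                        "fraction_remaining": np.exp(ln_frac),
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out


@dataclass
class QPCRSimConfig:
    """Conditions for a simulated qPCR plate."""

    wells_per_group: int = 4
    ct_target_control: float = 22.0
    ct_housekeeping: float = 16.0
    noise_sd_ct: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.wells_per_group <= 0:
            raise ValueError("wells_per_group must be positive")
        if self.noise_sd_ct < 0:
            raise ValueError("noise_sd_ct must be non-negative")


def gen_qpcr_plate(knockdown_fraction: float, config: QPCRSimConfig = QPCRSimConfig()) -> pd.DataFrame:
    """Simulate raw Ct values for one treated group against a control.

    With zero Ct noise, ddCt processing of the returned plate yields exactly
    ``1 - knockdown_fraction`` remaining: the treated target Ct is shifted up
    by ``-log2(1 - knockdown)`` cycles relative to control.

    Returns a DataFrame with columns ``sample`` ("treated"/"control"),
    ``well``, ``ct_target``, ``ct_housekeeping``.
    """
    if not 0.0 <= knockdown_fraction < 1.0:
        raise ValueError(f"knockdown_fraction must be in [0, 1), got {knockdown_fraction}")
    rng = np.random.default_rng(config.seed)
    shift = -np.log2(1.0 - knockdown_fraction)
    rows = []
    for sample, ct_t in (("control", config.ct_target_control),
                         ("treated", config.ct_target_control + shift)):
        for w in range(1, config.wells_per_group + 1):
            rows.append(
                {
                    "sample": sample,
                    "well": f"{sample[:1].upper()}{w}",
                    "ct_target": ct_t + rng.normal(0.0, config.noise_sd_ct),
                    "ct_housekeeping": config.ct_housekeeping
                    + rng.normal(0.0, config.noise_sd_ct),
                }
            )
    return pd.DataFrame(rows)


# planted semilog laws: knockdown% = a + b*log10(loading ng/g), chosen so the
# planted dose-response has realistic GalNAc-siRNA potency (parent-like
# EC50 0.066 / EC80 0.24 ng/g; advanced-design-like EC50 0.046 / EC80 0.20)
def _semilog_from_ec(ec50: float, ec80: float) -> tuple:
    b = 30.0 / (np.log10(ec80) - np.log10(ec50))
    a = 50.0 - b * np.log10(ec50)
    return a, b


_PARENT_A, _PARENT_B = _semilog_from_ec(0.066, 0.24)
_DV18_A, _DV18_B = _semilog_from_ec(0.046, 0.20)


@dataclass
class PKPDSimConfig:
    """Conditions for one synthetic in vivo PK/PD time course.

    The knockdown curve is K(t) = kd_max*(1-exp(-k_on*t))*exp(-k_off*t)
    (onset, nadir, slow recovery); Ago2 antisense loading is the inverse of
    the planted semilog law at each sampled day.  Days follow the original
    sampling scheme (4 hr then days 3, 7, 14, 21, 35) with 3 animals per
    time point.
    """

    group: str = "parent"
    kd_max: float = 0.93
    k_on: float = 1.2  # /day
    k_off: float = 0.03  # /day
    days: Sequence[float] = (0.0, 0.17, 3.0, 7.0, 14.0, 21.0, 35.0)
    animals_per_timepoint: int = 3
    semilog_a: float = _PARENT_A
    semilog_b: float = _PARENT_B
    noise_sd_ln: float = 0.10
    #: background sense-strand loading (ng/g); sense loading is flat noise
    #: near the detection limit
    sense_background: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.kd_max < 1.0:
            raise ValueError("kd_max must lie in [0, 1)")
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("k_on and k_off must be positive")
        if self.semilog_b == 0:
            raise ValueError("semilog_b must be non-zero (loading not invertible)")
        if self.animals_per_timepoint <= 0:
            raise ValueError("animals_per_timepoint must be positive")
        if self.noise_sd_ln < 0:
            raise ValueError("noise_sd_ln must be non-negative")

    def knockdown_curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.kd_max * (1.0 - np.exp(-self.k_on * t)) * np.exp(-self.k_off * t)

    def loading_curve(self, t: np.ndarray) -> np.ndarray:
        """Noise-free Ago2 antisense loading implied by the semilog law."""
        kd_pct = 100.0 * self.knockdown_curve(t)
        return 10.0 ** ((kd_pct - self.semilog_a) / self.semilog_b)


def parent_pkpd_config(seed: int = 0, **overrides) -> PKPDSimConfig:
    """Parent-like conditions (EC50 0.066, EC80 0.24 ng/g; fast recovery)."""
    cfg = PKPDSimConfig(group="parent", seed=seed, k_off=0.06,
                        semilog_a=_PARENT_A, semilog_b=_PARENT_B)
    return replace(cfg, **overrides) if overrides else cfg


def dv18_pkpd_config(seed: int = 0, **overrides) -> PKPDSimConfig:
    """Advanced-design-like conditions (EC50 0.046, EC80 0.20; slow recovery)."""
    cfg = PKPDSimConfig(group="DV18", seed=seed, k_off=0.015,
                        semilog_a=_DV18_A, semilog_b=_DV18_B)
    return replace(cfg, **overrides) if overrides else cfg


def gen_pkpd_timecourse(config: PKPDSimConfig) -> tuple:
    """Generate (mRNA time course, Ago2 loading table) for one dose group.

    Returns ``(mrna, loading)``:

    * ``mrna`` — columns ``group, animal, day, value`` with value = % of
      control mRNA, 100*(1-K(t)) times lognormal noise; expectation 100 at
      day 0.
    * ``loading`` — columns ``group, animal, day, strand, loading`` in ng
      strand per g liver; the antisense rows satisfy the planted semilog law
      up to lognormal noise, sense rows are flat background.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(list(config.days), dtype=float)
    n_animals = config.animals_per_timepoint
    kd = config.knockdown_curve(days)
    load_as = config.loading_curve(days)

    mrna_rows = []
    load_rows = []
    for j, day in enumerate(days):
        for a in range(1, n_animals + 1):
            animal = f"{config.group}_d{day:g}_a{a}"
            pct = 100.0 * (1.0 - kd[j]) * np.exp(rng.normal(0.0, config.noise_sd_ln))
            mrna_rows.append(
                {"group": config.group, "animal": animal, "day": day, "value": pct}
            )
            l_as = load_as[j] * np.exp(rng.normal(0.0, config.noise_sd_ln))
            l_s = config.sense_background * np.exp(rng.normal(0.0, config.noise_sd_ln))
            load_rows.append(
                {"group": config.group, "animal": animal, "day": day,
                 "strand": "antisense", "loading": l_as}
            )
            load_rows.append(
                {"group": config.group, "animal": animal, "day": day,
                 "strand": "sense", "loading": l_s}
            )
    return pd.DataFrame(mrna_rows), pd.DataFrame(load_rows)


def gen_dv_records(
    dv_effects: dict,
    reference: str = "parent",
    n_sites: int = 4,
    doses_nM: Sequence[float] = (10.0, 0.1),
    replicates: int = 4,
    baseline_ln: Optional[dict] = None,
    site_sd: float = 0.30,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a directed design-variant comparison panel.

    ``dv_effects`` maps DV label -> planted ln-difference vs the reference
    design (the reference itself is implicitly 0 and need not be listed).
    Each DV is measured at every site x dose x replicate cell, with ln
    fraction = dose baseline + site effect + DV effect + Normal noise.
    """
    rng = np.random.default_rng(seed)
    if baseline_ln is None:
        baseline_ln = {10.0: -1.6, 0.1: -0.6}
    effects = {reference: 0.0, **{k: float(v) for k, v in dv_effects.items()}}
    site_eff = rng.normal(0.0, site_sd, size=n_sites)
    rows = []
    for dv, eff in effects.items():
        for s in range(n_sites):
            for dose in doses_nM:
                for rep in range(1, replicates + 1):
                    ln_f = (
                        baseline_ln[float(dose)]
                        + site_eff[s]
                        + eff
                        + rng.normal(0.0, noise_sd)
                    )
                    rows.append(
                        {
                            "dv_id": dv,
                            "site_id": f"S{s + 1}",
                            "dose_nM": float(dose),
                            "replicate": rep,
                            "fraction_remaining": float(np.exp(ln_f)),
                        }
                    )
    return pd.DataFrame(rows)
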