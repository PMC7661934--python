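"""Synthetic clinical-impedance dataset and electrode permutations.

Emulates the structure of a clinical impedance collection from directional
leads: 12 subjects x 2 leads, 2 directional levels x 3 electrodes per lead,
7 visits, 980 retained measurements.  Impedances are drawn from a truncated
normal (default mean 2.99 kOhm) with optional AR(1) visit-to-visit
correlation per electrode (Gaussian copula, so the marginal stays exactly
truncated-normal).  The default missingness structure - 326 complete
three-electrode (lead, level, visit) groups plus exactly one two-electrode
group - is the unique composition consistent with 980 measurements, 1958
ordered within-level pairs and 978 ring-mode role permutations; it is
configurable.

This module generates synthetic stand-in data only; it does not contain or
reproduce any clinical measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .energy import (EnergyParams, current_draw_micc, current_draw_interleaving,
                     current_draw_coactivation)

__all__ = ["ImpedanceConfig", "ImpedanceDataset", "generate_dataset",
           "enumerate_pair_permutations", "enumerate_ring_permutations",
           "clinical_scenario_currents"]

COLUMNS = ["subject", "lead", "level", "electrode", "visit", "impedance_kohm"]


@dataclass(frozen=True)
class ImpedanceConfig:
    """Generator configuration (impedances in kOhm)."""

    n_subjects: int = 12
    leads_per_subject: int = 2
    levels_per_lead: int = 2
    electrodes_per_level: int = 3
    n_visits: int = 7
    mean_kohm: float = 2.99
    sd_kohm: float = 0.60
    min_kohm: float = 0.30
    visit_correlation: float = 0.8
    n_missing_groups: int = 9     # (lead, level, visit) groups with no measurement
    n_partial_groups: int = 1     # groups with exactly one electrode missing

    def __post_init__(self) -> None:
        if self.mean_kohm <= self.min_kohm:
            raise ValueError("mean impedance must exceed the truncation bound")
        if not (0.0 <= self.visit_correlation < 1.0):
            raise ValueError("visit correlation must be in [0, 1)")
        if self.n_missing_groups + self.n_partial_groups > self.total_groups:
            raise ValueError("missingness spec exceeds the number of groups")

    @property
    def total_groups(self) -> int:
        return (self.n_subjects * self.leads_per_subject
                * self.levels_per_lead * self.n_visits)

    @property
    def expected_records(self) -> int:
        complete = self.total_groups - self.n_missing_groups - self.n_partial_groups
        return (complete * self.electrodes_per_level
                + self.n_partial_groups * (self.electrodes_per_level - 1))


@dataclass
class ImpedanceDataset:
    """Long-format impedance records plus the generating configuration."""

    records: pd.DataFrame
    config: ImpedanceConfig = field(default_factory=ImpedanceConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        if (self.records["impedance_kohm"] <= 0).any():
            raise ValueError("impedances must be positive")
        keys = self.records[["lead", "level", "electrode", "visit"]]
        if keys.duplicated().any():
            raise ValueError("(lead, level, electrode, visit) must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def groups(self):
        """Iterate (key, subframe) over (lead, level, visit) groups."""
        return self.records.groupby(["lead", "level", "visit"], sort=True)

    def to_csv(self, path) -> None:
        self.records[COLUMNS].to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path, config: ImpedanceConfig | None = None,
                 seed: int | None = None) -> "ImpedanceDataset":
        df = pd.read_csv(path)
        return cls(df, config or ImpedanceConfig(), seed)


def generate_dataset(config: ImpedanceConfig | None = None,
                     seed: int = 0) -> ImpedanceDataset:
    """Generate the structured synthetic impedance dataset, deterministically.

    Per electrode, a latent AR(1) standard-normal series over visits is mapped
    through the Gaussian copula to a truncated normal
    ``TN(mean, sd; > min_kohm)``, so the marginal distribution is exact while
    consecutive visits are correlated.  Whole-group and single-electrode
    missingness are then applied per the configuration.
    """
    config = config or ImpedanceConfig()
    rng = np.random.default_rng(seed)
    c = config

    n_series = (c.n_subjects * c.leads_per_subject * c.levels_per_lead
                * c.electrodes_per_level)
    # latent AR(1), one row per electrode series, columns = visits
    z = np.empty((n_series, c.n_visits))
    z[:, 0] = rng.standard_normal(n_series)
    rho = c.visit_correlation
    for t in range(1, c.n_visits):
        z[:, t] = rho * z[:, t - 1] + np.sqrt(1.0 - rho ** 2) \
            * rng.standard_normal(n_series)
    a = (c.min_kohm - c.mean_kohm) / c.sd_kohm
    imped = stats.truncnorm.ppf(stats.norm.cdf(z), a, np.inf,
                                loc=c.mean_kohm, scale=c.sd_kohm)

    rows = []
    s_idx = 0
    for subj in range(1, c.n_subjects + 1):
        for lead_i in range(1, c.leads_per_subject + 1):
            lead_id = (subj - 1) * c.leads_per_subject + lead_i
            for level in range(1, c.levels_per_lead + 1):
                for elec in range(1, c.electrodes_per_level + 1):
                    for visit in range(1, c.n_visits + 1):
                        rows.append((subj, lead_id, level, elec, visit,
                                     imped[s_idx, visit - 1]))
                    s_idx += 1
    df = pd.DataFrame(rows, columns=COLUMNS)

    # missingness: drop whole groups, then one electrode from partial groups
    group_keys = df[["lead", "level", "visit"]].drop_duplicates().reset_index(drop=True)
    n_drop = c.n_missing_groups + c.n_partial_groups
    chosen = rng.choice(len(group_keys), size=n_drop, replace=False)
    full_missing = set(map(tuple, group_keys.iloc[chosen[:c.n_missing_groups]]
                           .to_numpy()))
    partial = [tuple(r) for r in group_keys.iloc[chosen[c.n_missing_groups:]]
               .to_numpy()]

    key = list(zip(df["lead"], df["level"], df["visit"]))
    keep = np.array([k not in full_missing for k in key])
    for k in partial:
        elec_gone = int(rng.integers(1, c.electrodes_per_level + 1))
        keep &= ~((df["lead"] == k[0]) & (df["level"] == k[1])
                  & (df["visit"] == k[2]) & (df["electrode"] == elec_gone))
    df = df[keep].reset_index(drop=True)

    if len(df) != c.expected_records:
        raise RuntimeError("missingness application produced an inconsistent count")
    return ImpedanceDataset(df, config=c, seed=seed)


def enumerate_pair_permutations(ds: ImpedanceDataset) -> pd.DataFrame:
    """All ordered pairs of distinct measured electrodes within each
    (lead, level, visit) group; k measured electrodes yield k*(k-1) pairs."""
    rows = []
    for (lead, level, visit), g in ds.groups():
        elecs = list(zip(g["electrode"], g["impedance_kohm"]))
        for (ea, za), (eb, zb) in permutations(elecs, 2):
            rows.append((lead, level, visit, ea, eb, za, zb))
    return pd.DataFrame(rows, columns=["lead", "level", "visit",
                                       "electrode_a", "electrode_b",
                                       "z_a_kohm", "z_b_kohm"])


def enumerate_ring_permutations(ds: ImpedanceDataset) -> pd.DataFrame:
    """For each complete three-electrode group, the three assignments of the
    dominant (-34%) role; incomplete groups contribute none."""
    n_full = ImpedanceConfig().electrodes_per_level if ds.config is None \
        else ds.config.electrodes_per_level
    rows = []
    for (lead, level, visit), g in ds.groups():
        if len(g) != n_full:
            continue
        elecs = list(zip(g["electrode"], g["impedance_kohm"]))
        for i, (e_dom, z_dom) in enumerate(elecs):
            others = [z for j, (_, z) in enumerate(elecs) if j != i]
            rows.append((lead, level, visit, e_dom, z_dom, others[0], others[1]))
    return pd.DataFrame(rows, columns=["lead", "level", "visit",
                                       "dominant_electrode", "z_dom_kohm",
                                       "z_other1_kohm", "z_other2_kohm"])


def clinical_scenario_currents(ds: ImpedanceDataset, settings: list[dict],
                               params: EnergyParams | None = None) -> pd.DataFrame:
    """Current draw across electrode permutations for each stimulation setting.

    Each setting dict holds ``label``, ``target_radius_mm`` and either
    fractionalization amplitudes (``fractions`` as two magnitudes summing to
    100, ``micc_total_mA``, ``interleaving_total_mA``) or a ring-mode spec
    (``ring=True``, ``micc_total_mA``).  MICC and Interleaving are evaluated
    on every ordered pair (or every ring role permutation); coactivation only
    for uniform splits, where a single source divides current by impedance.
    Returns per-setting, per-paradigm mean +/- sd over permutations.
    """
    params = params or EnergyParams()
    pairs = enumerate_pair_permutations(ds)
    rings = enumerate_ring_permutations(ds)
    za = pairs["z_a_kohm"].to_numpy()
    zb = pairs["z_b_kohm"].to_numpy()

    out = []

    def summarize(label, radius, paradigm, values):
        v = np.asarray(values, float)
        out.append({"label": label, "target_radius_mm": radius,
                    "paradigm": paradigm, "mean_uA": float(v.mean()),
                    "sd_uA": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                    "n_permutations": int(v.size)})

    for s in settings:
        label, radius = s["label"], s.get("target_radius_mm")
        if s.get("ring"):
            a_tot = s["micc_total_mA"]
            f = np.array([0.34, 0.33, 0.33])
            vals = [current_draw_micc(a_tot * f,
                                      [r.z_dom_kohm, r.z_other1_kohm, r.z_other2_kohm],
                                      params)
                    for r in rings.itertuples()]
            summarize(label, radius, "micc", vals)
            zz = rings[["z_dom_kohm", "z_other1_kohm", "z_other2_kohm"]].to_numpy()
            vals = [current_draw_coactivation(a_tot, z, params) for z in zz]
            summarize(label, radius, "coactivation", vals)
            continue

        f1, f2 = (abs(x) / 100.0 for x in s["fractions"])
        if abs(f1 + f2 - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 100% in magnitude")
        a_micc = s["micc_total_mA"]
        vals = [current_draw_micc([a_micc * f1, a_micc * f2], [x, y], params)
                for x, y in zip(za, zb)]
        summarize(label, radius, "micc", vals)
        a_int = s.get("interleaving_total_mA")
        if a_int is not None:
            vals = [current_draw_interleaving([a_int * f1, a_int * f2], [x, y],
                                              params)
                    for x, y in zip(za, zb)]
            summarize(label, radius, "interleaving", vals)
        if abs(f1 - f2) < 1e-12:  # uniform split: coactivation comparable
            vals = [current_draw_coactivation(a_micc, [x, y], params)
                    for x, y in zip(za, zb)]
            summarize(label, radius, "coactivation", vals)

    return pd.DataFrame(out)
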