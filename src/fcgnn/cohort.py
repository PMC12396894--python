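"""Synthetic case–control cohorts of functional-connectivity matrices.

Emulates a matched patient/control resting-state fMRI study at desk scale:
two groups of subjects, each described by a region-by-region Fisher-z
connectivity matrix with block structure following canonical large-scale
networks, a configurable set of "planted" connections whose correlation
differs between groups, and clinical scores linearly coupled to designated
connections plus noise.

The generator samples a multivariate-normal BOLD-like time series per
subject from a block-structured target correlation matrix, then computes
the Pearson correlation of that finite series and Fisher-transforms it —
so the matrices carry the same estimation noise structure as real FC
estimates (the series length ``T`` controls the noise level: the Fisher-z
of a sample correlation is approximately normal with variance
``1/(T - 3)``). The self-connection is set to 0 before any downstream use,
since the Fisher z of r = 1 is infinite.

Defaults describe a realistic resting-state cohort: 100 regions grouped
into the eight canonical networks of the packaged parcel table, within-
network correlation 0.4, between-network correlation 0.1, 150 time points
per subject, 100 subjects per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, ParcelTable

_EIG_FLOOR = 1e-8


class CovarianceError(ValueError):
    """Target covariance could not be made positive definite."""


@dataclass(frozen=True)
class PlantedEffect:
    """A group difference: patients' target correlation on (i, j) is
    shifted by ``delta`` relative to controls."""

    i: int
    j: int
    delta: float


@dataclass(frozen=True)
class ClinicalCoupling:
    """Linear score model: score = slope * FC(i, j) + intercept + N(0, sd)."""

    i: int
    j: int
    slope: float
    intercept: float = 0.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Conditions for one synthetic cohort. See module docstring for the
    rationale behind the defaults."""

    n_per_group: int = 100
    n_regions: int = 100
    series_length: int = 150
    network_assignment: tuple[str, ...] | None = None
    base_within: float = 0.4
    base_between: float = 0.1
    planted_effects: tuple[PlantedEffect, ...] = ()
    noise_sd: float = 0.0
    clinical_couplings: dict = field(default_factory=dict)  # name -> ClinicalCoupling
    site_offset: float = 0.0  # optional additive site effect, off by default
    n_sites: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group <= 0 or self.n_regions <= 0 or self.series_length <= 0:
            raise ValueError("n_per_group, n_regions, series_length must be positive")
        if not (-1 < self.base_within < 1 and -1 < self.base_between < 1):
            raise ValueError("base correlations must lie in (-1, 1)")
        for eff in self.planted_effects:
            if eff.i == eff.j:
                raise ValueError(f"planted effect on diagonal: ({eff.i}, {eff.j})")
            if not (0 <= eff.i < self.n_regions and 0 <= eff.j < self.n_regions):
                raise ValueError(f"planted effect indices out of range: {eff}")
            base = (self.base_within
                    if self._same_block(eff.i, eff.j) else self.base_between)
            if abs(base + eff.delta) >= 1:
                raise ValueError(
                    f"planted |base + delta| = {abs(base + eff.delta)} >= 1 for {eff}"
                )
        for name, c in self.clinical_couplings.items():
            if not (0 <= c.i < self.n_regions and 0 <= c.j < self.n_regions) or c.i == c.j:
                raise ValueError(f"coupling {name!r} references invalid edge ({c.i},{c.j})")

    # -- block structure ---------------------------------------------------
    def assignment(self) -> tuple[str, ...]:
        """Region -> network-group label; defaults to the packaged parcel
        table when n_regions == 100, else 8 contiguous equal blocks."""
        if self.network_assignment is not None:
            if len(self.network_assignment) != self.n_regions:
                raise ValueError("network_assignment length != n_regions")
            return tuple(self.network_assignment)
        if self.n_regions == 100:
            return ParcelTable.schaefer100().network_group
        from .connectome import NETWORK_GROUPS
        bounds = np.linspace(0, self.n_regions, len(NETWORK_GROUPS) + 1).astype(int)
        out = []
        for g, (lo, hi) in zip(NETWORK_GROUPS, zip(bounds[:-1], bounds[1:])):
            out.extend([g] * (hi - lo))
        return tuple(out)

    def _same_block(self, i: int, j: int) -> bool:
        a = self.assignment()
        return a[i] == a[j]

    # -- analytic targets --------------------------------------------------
    def target_correlation(self, group: str) -> np.ndarray:
        """Block-structured target correlation matrix for one group,
        before positive-definite repair."""
        a = np.asarray(self.assignment())
        C = np.where(a[:, None] == a[None, :], self.base_within, self.base_between)
        np.fill_diagonal(C, 1.0)
        if group == "patient":
            for eff in self.planted_effects:
                C[eff.i, eff.j] += eff.delta
                C[eff.j, eff.i] += eff.delta
        elif group != "control":
            raise ValueError(f"unknown group {group!r}")
        return C

    def expected_correlation(self, group: str) -> np.ndarray:
        """Population correlation of the *observed* series (after PD repair
        and measurement-noise attenuation)."""
        C = _repair_pd(self.target_correlation(group), self.planted_effects)
        if self.noise_sd > 0:
            C = C / (1.0 + self.noise_sd**2)
            np.fill_diagonal(C, 1.0)
        return C


@dataclass
class SubjectRecord:
    """Demographics and (possibly missing) clinical scores for one subject."""

    subject_id: str
    group: str                       # "patient" | "control"
    age: float
    sex: str                         # "M" | "F"
    site: str
    clinical_scores: dict = field(default_factory=dict)  # name -> float | None

    def __post_init__(self):
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be patient/control, got {self.group!r}")


def _repair_pd(C: np.ndarray, effects=()) -> np.ndarray:
    """Nearest-positive-definite repair by eigenvalue clipping, followed by
    re-normalization to unit diagonal. Fatal if repair fails."""
    w, V = np.linalg.eigh(C)
    if w.min() >= _EIG_FLOOR:
        return C
    w = np.clip(w, _EIG_FLOOR, None)
    R = (V * w) @ V.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    if np.linalg.eigvalsh(R).min() <= 0:
        raise CovarianceError(
            "target covariance not positive definite after eigenvalue-clipping "
            f"repair; planted effects involved: {list(effects)}"
        )
    return R


def _fisher_z_safe(r: np.ndarray) -> np.ndarray:
    # sample correlations can round to +/-1 only degenerately; clip for safety
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], list[ConnectivityMatrix]]:
    """Sample a matched two-group cohort.

    Deterministic given ``spec.seed``. Controls are generated first, then
    patients matched one-to-one on sex and site with age within +/-2 years.
    If ``spec.clinical_couplings`` is non-empty, scores are filled for
    patients (the group in which clinical scales are measured).

    Returns (subjects, matrices), both ordered controls then patients.
    """
    rng = np.random.default_rng(spec.seed)
    n, T = spec.n_regions, spec.series_length

    chols = {}
    for group in ("control", "patient"):
        C = _repair_pd(spec.target_correlation(group), spec.planted_effects)
        chols[group] = np.linalg.cholesky(C)

    subjects: list[SubjectRecord] = []
    matrices: list[ConnectivityMatrix] = []
    # matched demographics: draw for the control, mirror for the patient
    ages = np.clip(rng.normal(40.0, 12.0, spec.n_per_group), 18, 70)
    sexes = rng.choice(["M", "F"], spec.n_per_group)
    sites = [f"site{1 + i % spec.n_sites:02d}" for i in range(spec.n_per_group)]
    age_jitter = rng.uniform(-2.0, 2.0, spec.n_per_group)

    site_shift = {f"site{s + 1:02d}": spec.site_offset * s for s in range(spec.n_sites)}

    for group in ("control", "patient"):
        L = chols[group]
        for idx in range(spec.n_per_group):
            ts = rng.standard_normal((T, n)) @ L.T
            if spec.noise_sd > 0:
                ts = ts + spec.noise_sd * rng.standard_normal((T, n))
            if spec.site_offset:
                ts = ts + site_shift[sites[idx]]
            r = np.corrcoef(ts, rowvar=False)
            z = _fisher_z_safe(r)
            np.fill_diagonal(z, 0.0)
            z = (z + z.T) / 2.0  # exact symmetry against fp asymmetry
            tag = "pat" if group == "patient" else "con"
            sid = f"sub-{tag}{idx:03d}"
            age = ages[idx] + (age_jitter[idx] if group == "patient" else 0.0)
            subjects.append(SubjectRecord(sid, group, float(np.clip(age, 18, 72)),
                                          str(sexes[idx]), sites[idx]))
            matrices.append(ConnectivityMatrix(z, subject_id=sid))

    if spec.clinical_couplings:
        patients = [s for s in subjects if s.group == "patient"]
        pmats = [m for s, m in zip(subjects, matrices) if s.group == "patient"]
        generate_clinical_scores(patients, pmats, spec.clinical_couplings,
                                 seed=int(rng.integers(2**31)))
    return subjects, matrices


def generate_clinical_scores(subjects: list[SubjectRecord],
                             matrices: list[ConnectivityMatrix],
                             couplings: dict,
                             seed: int,
                             missing_rate: float = 0.0) -> list[SubjectRecord]:
    """Fill ``clinical_scores`` in place: score = slope*FC(i,j) + intercept + noise.

    ``missing_rate`` marks scores missing at random (scores are often
    available only for a subset of patients). Returns the subject list.
    """
    if len(subjects) != len(matrices):
        raise ValueError("subjects and matrices must align")
    rng = np.random.default_rng(seed)
    n = matrices[0].n_regions if matrices else 0
    for name, c in couplings.items():
        if not (0 <= c.i < n and 0 <= c.j < n) or c.i == c.j:
            raise ValueError(f"coupling {name!r} references missing edge ({c.i},{c.j})")
    for sub, mat in zip(subjects, matrices):
        for name, c in couplings.items():
            fc = mat.values[c.i, c.j]
            val = c.slope * fc + c.intercept + (
                rng.normal(0.0, c.noise_sd) if c.noise_sd > 0 else 0.0)
            if missing_rate > 0 and rng.random() < missing_rate:
                sub.clinical_scores[name] = None
            else:
                sub.clinical_scores[name] = float(val)
    return subjects


def coupling_for_target_r(spec: CohortSpec, i: int, j: int, r: float,
                          slope: float = 50.0, intercept: float = 20.0) -> ClinicalCoupling:
    """Coupling whose population correlation with FC(i, j) is ``r``.

    Uses the large-sample approximation sd(Fisher-z FC) = 1/sqrt(T - 3) to
    set the score noise: noise_sd = |slope| * sd_FC * sqrt(1/r^2 - 1).
    """
    if not 0 < abs(r) < 1:
        raise ValueError("target r must lie in (0, 1) in magnitude")
    if spec.series_length <= 3:
        raise ValueError("series_length must exceed 3")
    sd_fc = 1.0 / np.sqrt(spec.series_length - 3)
    noise = abs(slope) * sd_fc * np.sqrt(1.0 / r**2 - 1.0)
    return ClinicalCoupling(i=i, j=j, slope=np.sign(r) * abs(slope),
                            intercept=intercept, noise_sd=float(noise))


# ---------------------------------------------------------------------------
# cohort I/O: one header-free TSV matrix per subject + a subjects table
# ---------------------------------------------------------------------------

def write_cohort(subjects: list[SubjectRecord], matrices: list[ConnectivityMatrix],
                 out_dir) -> None:
    """Write matrices as ``<subject_id>.tsv`` plus ``subjects.tsv``.

    Floats are written with 17 significant digits so the reader
    round-trips bitwise."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    score_names = sorted({k for s in subjects for k in s.clinical_scores})
    rows = []
    for sub, mat in zip(subjects, matrices):
        np.savetxt(out / f"{sub.subject_id}.tsv", mat.values,
                   delimiter="\t", fmt="%.17g")
        row = {"subject_id": sub.subject_id, "group": sub.group,
               "age": repr(sub.age), "sex": sub.sex, "site": sub.site}
        for name in score_names:
            v = sub.clinical_scores.get(name)
            row[name] = "" if v is None else repr(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)


def read_cohort(in_dir) -> tuple[list[SubjectRecord], list[ConnectivityMatrix]]:
    """Inverse of :func:`write_cohort`."""
    from pathlib import Path
    src = Path(in_dir)
    df = pd.read_csv(src / "subjects.tsv", sep="\t", dtype={"subject_id": str},
                     float_precision="round_trip")
    meta_cols = {"subject_id", "group", "age", "sex", "site"}
    score_names = [c for c in df.columns if c not in meta_cols]
    subjects, matrices = [], []
    for _, row in df.iterrows():
        scores = {}
        for name in score_names:
            v = row[name]
            scores[name] = None if pd.isna(v) else float(v)
        subjects.append(SubjectRecord(row["subject_id"], row["group"],
                                      float(row["age"]), row["sex"], row["site"],
                                      clinical_scores=scores))
        vals = np.loadtxt(src / f"{row['subject_id']}.tsv", delimiter="\t")
        matrices.append(ConnectivityMatrix(vals, subject_id=row["subject_id"]))
    return subjects, matrices
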