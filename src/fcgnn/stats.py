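"""Network attribution of top-ranked connections and clinical correlation.

Two reporting stages sit downstream of the perturbation ranking:

* **Network attribution** — each of the top-k connections contributes its
  two region endpoints (with multiplicity: a region appearing in several
  connections is counted each time), and the 2k endpoint slots are
  tallied by large-scale network group. Percentages are count / (2k) x 100.

* **Clinical correlation** — each top connection's FC values are
  correlated with each clinical score across subjects with a non-missing
  score (pairwise deletion). Pearson correlation is used unless either
  variable fails a Shapiro-Wilk normality test at alpha = 0.05, in which
  case Spearman is used; the chosen method is recorded per test.
  Bonferroni correction uses the family size m = (number of scores) x
  (number of connections), recomputed from the report contents.

The two published top-20 connection lists (for the depression and
schizophrenia classifiers) ship with the package and can be loaded with
:func:`published_top20`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectome import ConnectivityMatrix, ParcelTable, NETWORK_GROUPS, network_group_of
from .cohort import SubjectRecord
from .explain import ConnectionRanking

ALPHA = 0.05


def published_top20(disorder: str) -> list[tuple[str, str]]:
    """The packaged top-20 connection list ('mdd' or 'sz') as region-name
    pairs, in rank order."""
    disorder = disorder.lower()
    if disorder not in ("mdd", "sz"):
        raise ValueError(f"disorder must be 'mdd' or 'sz', got {disorder!r}")
    with resources.as_file(
        resources.files("fcgnn.data") / f"top20_{disorder}.tsv"
    ) as p:
        df = pd.read_csv(p, sep="\t").sort_values("rank")
    return list(zip(df["region_i"], df["region_j"]))


@dataclass
class AttributionReport:
    """Network-group tallies over the 2k endpoints of the top-k connections."""

    counts: dict                # network_group -> int
    percentages: dict           # network_group -> percent of 2k
    k: int
    disorder_label: str = ""

    def __post_init__(self):
        total = sum(self.counts.values())
        if total != 2 * self.k:
            raise ValueError(f"endpoint counts sum to {total}, expected {2 * self.k}")
        if abs(sum(self.percentages.values()) - 100.0) > 1e-9:
            raise ValueError("percentages must sum to 100")


def _as_name_pairs(connections, table: ParcelTable) -> list[tuple[str, str]]:
    if isinstance(connections, ConnectionRanking):
        return [(table.names[i], table.names[j])
                for i, j in connections.top_pairs()]
    out = []
    for a, b in connections:
        if isinstance(a, (int, np.integer)):
            out.append((table.names[int(a)], table.names[int(b)]))
        else:
            out.append((a, b))
    return out


def attribute_networks(connections, table: ParcelTable,
                       disorder_label: str = "") -> AttributionReport:
    """Tally the network groups of the endpoints of ranked connections.

    ``connections`` is a :class:`ConnectionRanking` (its top-k slice is
    used) or an explicit list of region-name or region-index pairs.
    Endpoints are counted with multiplicity so the tallies sum to 2k.
    """
    pairs = _as_name_pairs(connections, table)
    counts = {g: 0 for g in NETWORK_GROUPS}
    for a, b in pairs:
        counts[network_group_of(a, table)] += 1
        counts[network_group_of(b, table)] += 1
    k = len(pairs)
    perc = {g: 100.0 * c / (2 * k) for g, c in counts.items()}
    return AttributionReport(counts=counts, percentages=perc, k=k,
                             disorder_label=disorder_label)


@dataclass
class CorrelationResult:
    """One connection-score correlation test."""

    pair: tuple                 # (region_name_i, region_name_j)
    score_name: str
    method: str                 # "pearson" | "spearman" | "undefined"
    r: float
    p_raw: float
    p_corrected: float
    n: int
    note: str = ""


def correlate_clinical(subjects: list[SubjectRecord],
                       matrices: list[ConnectivityMatrix],
                       connections, table: ParcelTable,
                       score_names: list[str],
                       alpha: float = ALPHA) -> list[CorrelationResult]:
    """Correlate each top connection with each clinical score.

    Subjects with a missing score are dropped per test (pairwise
    deletion); each test needs at least 3 complete observations. The
    Shapiro-Wilk gate (either variable non-normal at ``alpha`` ->
    Spearman) and the Bonferroni family m = scores x connections follow
    the reporting protocol in the module docstring.
    """
    if len(subjects) != len(matrices):
        raise ValueError("subjects and matrices must align")
    name_pairs = _as_name_pairs(connections, table)
    idx_pairs = [(table.index_of(a), table.index_of(b)) for a, b in name_pairs]
    m = len(score_names) * len(name_pairs)
    results: list[CorrelationResult] = []
    for score_name in score_names:
        have = [(s.clinical_scores.get(score_name), mat)
                for s, mat in zip(subjects, matrices)
                if s.clinical_scores.get(score_name) is not None]
        y_all = np.array([v for v, _ in have], dtype=float)
        for (a, b), (i, j) in zip(name_pairs, idx_pairs):
            x = np.array([mat.values[i, j] for _, mat in have])
            n = len(x)
            if n < 3:
                results.append(CorrelationResult(
                    (a, b), score_name, "undefined", float("nan"),
                    float("nan"), float("nan"), n,
                    note="fewer than 3 non-missing observations"))
                continue
            if np.ptp(x) == 0 or np.ptp(y_all) == 0:
                results.append(CorrelationResult(
                    (a, b), score_name, "undefined", float("nan"),
                    float("nan"), float("nan"), n,
                    note="constant variable; correlation undefined"))
                continue
            normal = (sps.shapiro(x).pvalue >= alpha
                      and sps.shapiro(y_all).pvalue >= alpha)
            if normal:
                r, p = sps.pearsonr(x, y_all)
                method = "pearson"
            else:
                r, p = sps.spearmanr(x, y_all)
                method = "spearman"
            results.append(CorrelationResult(
                (a, b), score_name, method, float(r), float(p),
                min(1.0, m * float(p)), n))
    return results


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

_SCHEMA_FILE = "report_schema.json"


def _load_schema() -> dict:
    with resources.as_file(resources.files("fcgnn.data") / _SCHEMA_FILE) as p:
        return json.loads(Path(p).read_text())


def validate_report(report: dict) -> None:
    """Structural validation against the packaged report schema (required
    keys and primitive types; raises ValueError on violation)."""
    schema = _load_schema()

    def check(obj, spec, path="report"):
        for key, sub in spec.get("required", {}).items():
            if key not in obj:
                raise ValueError(f"missing required key {path}.{key}")
            val = obj[key]
            t = sub.get("type")
            if t == "object":
                if not isinstance(val, dict):
                    raise ValueError(f"{path}.{key} must be an object")
                check(val, sub, f"{path}.{key}")
            elif t == "array" and not isinstance(val, list):
                raise ValueError(f"{path}.{key} must be an array")
            elif t == "number" and not isinstance(val, (int, float)):
                raise ValueError(f"{path}.{key} must be a number")
            elif t == "string" and not isinstance(val, str):
                raise ValueError(f"{path}.{key} must be a string")

    check(report, schema)


def render_report(attribution: AttributionReport,
                  correlations: list[CorrelationResult],
                  run_summary: dict | None,
                  out_dir,
                  config: dict | None = None,
                  seeds: list[int] | None = None) -> dict:
    """Write the machine-readable JSON report plus TSV and text renderings.

    Deterministic: no timestamps, so identical inputs give byte-identical
    output. Returns the report dict.
    """
    from . import __version__
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "version": __version__,
        "config": config or {},
        "seeds": list(seeds or []),
        "attribution": {
            "disorder_label": attribution.disorder_label,
            "k": attribution.k,
            "counts": dict(attribution.counts),
            "percentages": dict(attribution.percentages),
        },
        "correlations": [{
            "region_i": c.pair[0], "region_j": c.pair[1],
            "score": c.score_name, "method": c.method,
            "r": None if np.isnan(c.r) else c.r,
            "p_raw": None if np.isnan(c.p_raw) else c.p_raw,
            "p_corrected": None if np.isnan(c.p_corrected) else c.p_corrected,
            "n": c.n, "note": c.note,
        } for c in correlations],
        "run_summary": run_summary or {},
        "notes": [] if correlations else ["no clinical scores provided"],
    }
    validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(out / "attribution.tsv", "w") as fh:
        fh.write("network_group\tcount\tpercent\n")
        for g in NETWORK_GROUPS:
            fh.write(f"{g}\t{attribution.counts[g]}\t{attribution.percentages[g]:.10g}\n")
    with open(out / "correlations.tsv", "w") as fh:
        fh.write("region_i\tregion_j\tscore\tmethod\tr\tp_raw\tp_corrected\tn\tnote\n")
        for c in correlations:
            fh.write(f"{c.pair[0]}\t{c.pair[1]}\t{c.score_name}\t{c.method}\t"
                     f"{c.r:.10g}\t{c.p_raw:.10g}\t{c.p_corrected:.10g}\t{c.n}\t{c.note}\n")

    lines = [f"Connectome classification report ({attribution.disorder_label or 'unlabelled'})",
             "", f"Top-{attribution.k} connection network attribution "
             f"({2 * attribution.k} endpoints):"]
    for g in NETWORK_GROUPS:
        lines.append(f"  {g:>4}: {attribution.counts[g]:3d}  "
                     f"({attribution.percentages[g]:.1f}%)")
    if correlations:
        lines += ["", f"Clinical correlations ({len(correlations)} tests, "
                  "Bonferroni-corrected):"]
        for c in correlations:
            flag = " *" if (not np.isnan(c.p_corrected) and c.p_corrected < ALPHA) else ""
            lines.append(f"  {c.pair[0]} - {c.pair[1]} x {c.score_name}: "
                         f"{c.method} r={c.r:.3f}, p_corr={c.p_corrected:.3g}, "
                         f"n={c.n}{flag}")
    else:
        lines += ["", "No clinical scores provided."]
    if run_summary:
        lines += ["", "Run summary:"]
        for metric, s in run_summary.items():
            lines.append(f"  {metric}: mean {s['mean']:.3f} +/- SD {s['sd']:.3f} "
                         f"(range {s['min']:.3f}-{s['max']:.3f})")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report
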