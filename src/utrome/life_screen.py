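"""Dual-luciferase (3'LIFE-style) screen planning and repression analysis.

A test 3'UTR is fused to the firefly luciferase reporter and co-transfected
with either a query miRNA or a control; Renilla luciferase on the same
plasmid serves as the internal transfection control.  The repression index
(RI) of a 3'UTR for a miRNA is the replicate-paired ratio of normalized
luminescence:

    r(well)   = firefly / renilla
    RI_i      = r(query miRNA, replicate i) / r(control, replicate i)
    mean RI   = arithmetic mean over replicates

Replicate pairing cancels plate-level batch effects.  A 3'UTR is called a
repressed hit when mean RI falls below the repression cutoff (default 0.8)
with a two-sided one-sample t-test of log2(RI) against 0 significant at
alpha (default 0.05); enhancement is called symmetrically above the
reciprocal cutoff.  No multiple-testing correction is applied by default
(matching the raw p < 0.05 convention); Benjamini-Hochberg is available by
flag.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import normalize_dna, revcomp

__all__ = [
    "ScreenPlan",
    "RepressionResult",
    "ControlDesign",
    "plan_screen",
    "read_plate_tsv",
    "repression_index",
    "call_hits",
    "analyze_screen",
    "results_long_format",
    "design_mirna_controls",
    "PLATE_COLUMNS",
]

PLATE_COLUMNS = ["plate", "well", "utr_id", "mirna_id", "replicate", "firefly", "renilla"]


@dataclass
class ScreenPlan:
    layout: pd.DataFrame  # columns: plate, well, sample_id, role, replicate
    query_reactions: int
    control_reactions: int
    n_plates: int

    @property
    def total_reactions(self) -> int:
        return self.query_reactions + self.control_reactions


def _well_names(capacity: int) -> list[str]:
    rows, cols = (8, 12) if capacity == 96 else (16, 24)
    return [
        f"{r}{c}" for r in string.ascii_uppercase[:rows] for c in range(1, cols + 1)
    ]


def plan_screen(
    n_utrs: int, n_controls: int, n_replicates: int, plate_capacity: int = 96
) -> ScreenPlan:
    """Deterministic plate layout: row-major fill, query UTRs first,
    controls last, one plate set per replicate."""
    if n_utrs <= 0:
        raise ValueError("n_utrs must be positive")
    if n_controls < 0 or n_replicates < 0:
        raise ValueError("counts must be non-negative")
    if plate_capacity not in (96, 384):
        raise ValueError("plate_capacity must be 96 or 384")
    wells = _well_names(plate_capacity)
    samples = [(f"utr{i + 1:03d}", "query") for i in range(n_utrs)] + [
        (f"ctrl{i + 1}", "control") for i in range(n_controls)
    ]
    rows = []
    n_plates = 0
    for rep in range(1, n_replicates + 1):
        for i, (sid, role) in enumerate(samples):
            plate_no = i // plate_capacity + 1
            rows.append(
                {
                    "plate": f"rep{rep}_p{plate_no}",
                    "well": wells[i % plate_capacity],
                    "sample_id": sid,
                    "role": role,
                    "replicate": rep,
                }
            )
        n_plates += (len(samples) - 1) // plate_capacity + 1
    return ScreenPlan(
        layout=pd.DataFrame(rows),
        query_reactions=n_utrs * n_replicates,
        control_reactions=n_controls * n_replicates,
        n_plates=n_plates,
    )


def read_plate_tsv(path) -> pd.DataFrame:
    """Load plate measurements, validating the expected columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    return df


@dataclass
class RepressionResult:
    utr_id: str
    mirna_id: str
    replicate_ri: list[float]
    mean_ri: float
    n_replicates: int
    dropped_replicates: list[int] = field(default_factory=list)
    p_value: float = float("nan")
    verdict: str = ""
    flags: list[str] = field(default_factory=list)


def repression_index(
    measurements: pd.DataFrame,
    utr_id: str,
    query_mirna: str,
    control_mirna: str,
    paired: bool = True,
    renilla_floor: float = 0.0,
) -> RepressionResult:
    """Replicate repression indices for one 3'UTR.

    Wells with renilla at or below ``renilla_floor`` are dropped and their
    replicate recorded.  In paired mode each query replicate is divided by
    the control well of the same replicate; replicates present on only one
    side (and not explained by a drop) are an error.  In pooled mode query
    ratios are divided by the mean control ratio.
    """
    df = measurements[measurements["utr_id"] == utr_id]
    q = df[df["mirna_id"] == query_mirna]
    c = df[df["mirna_id"] == control_mirna]
    if q.empty or c.empty:
        raise ValueError(f"missing query or control wells for {utr_id!r}")

    dropped = sorted(
        set(q.loc[q["renilla"] <= renilla_floor, "replicate"])
        | set(c.loc[c["renilla"] <= renilla_floor, "replicate"])
    )
    q = q[q["renilla"] > renilla_floor]
    c = c[c["renilla"] > renilla_floor]
    if q.empty or c.empty:
        raise ValueError(f"no usable wells for {utr_id!r}")

    q_ratio = (q["firefly"] / q["renilla"]).to_numpy()
    c_ratio = (c["firefly"] / c["renilla"]).to_numpy()
    if paired:
        q_by_rep = dict(zip(q["replicate"], q_ratio))
        c_by_rep = dict(zip(c["replicate"], c_ratio))
        unpaired = (set(q_by_rep) ^ set(c_by_rep)) - set(dropped)
        if unpaired:
            raise ValueError(
                f"unpaired replicates {sorted(unpaired)} for {utr_id!r} in paired mode"
            )
        reps = sorted(set(q_by_rep) & set(c_by_rep))
        ris = [q_by_rep[r] / c_by_rep[r] for r in reps]
    else:
        ris = list(q_ratio / c_ratio.mean())
    if not ris:
        raise ValueError(f"no usable wells for {utr_id!r}")
    return RepressionResult(
        utr_id=utr_id,
        mirna_id=query_mirna,
        replicate_ri=[float(x) for x in ris],
        mean_ri=float(np.mean(ris)),
        n_replicates=len(ris),
        dropped_replicates=[int(r) for r in dropped],
    )


def call_hits(
    results: list[RepressionResult],
    repression_cutoff: float = 0.8,
    alpha: float = 0.05,
    enhancement_cutoff: float = 1.25,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Attach p-values and verdicts; return the hit table sorted by mean RI.

    The test is a two-sided one-sample t-test of per-replicate log2(RI)
    against 0 (log scale symmetrizes ratio noise).  Results with fewer than
    two replicates are flagged ``underpowered`` and never called.
    """
    pvals = np.full(len(results), np.nan)
    for i, res in enumerate(results):
        if res.n_replicates < 2:
            res.flags.append("underpowered")
            res.verdict = "none"
            continue
        pvals[i] = stats.ttest_1samp(np.log2(res.replicate_ri), 0.0).pvalue
    if bh_correct:
        ok = ~np.isnan(pvals)
        if ok.any():
            pvals[ok] = stats.false_discovery_control(pvals[ok], method="bh")
    for res, p in zip(results, pvals):
        res.p_value = float(p)
        if res.n_replicates < 2:
            continue
        if res.mean_ri < repression_cutoff and p < alpha:
            res.verdict = "repressed_hit"
        elif res.mean_ri > enhancement_cutoff and p < alpha:
            res.verdict = "enhanced"
        else:
            res.verdict = "none"
    table = pd.DataFrame(
        {
            "utr_id": [r.utr_id for r in results],
            "mirna_id": [r.mirna_id for r in results],
            "mean_ri": [r.mean_ri for r in results],
            "p_value": [r.p_value for r in results],
            "n_replicates": [r.n_replicates for r in results],
            "verdict": [r.verdict for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )
    return table.sort_values(
        ["mean_ri", "utr_id"], kind="mergesort"
    ).reset_index(drop=True)


def analyze_screen(
    measurements: pd.DataFrame,
    query_mirna: str,
    control_mirna: str,
    paired: bool = True,
    renilla_floor: float = 0.0,
    repression_cutoff: float = 0.8,
    alpha: float = 0.05,
    enhancement_cutoff: float = 1.25,
    bh_correct: bool = False,
) -> tuple[list[RepressionResult], pd.DataFrame]:
    """Repression indices and hit calls for every 3'UTR in a plate table."""
    results = [
        repression_index(sub, utr, query_mirna, control_mirna, paired, renilla_floor)
        for utr, sub in sorted(measurements.groupby("utr_id"), key=lambda kv: kv[0])
        if (sub["mirna_id"] == query_mirna).any()
    ]
    table = call_hits(
        results, repression_cutoff, alpha, enhancement_cutoff, bh_correct
    )
    return results, table


def results_long_format(results: list[RepressionResult]) -> pd.DataFrame:
    """Heat-map-ready long table: one row per (utr, mirna, replicate)."""
    rows = []
    for res in results:
        for i, ri in enumerate(res.replicate_ri, start=1):
            rows.append(
                {
                    "utr_id": res.utr_id,
                    "mirna_id": res.mirna_id,
                    "replicate": i,
                    "ri": ri,
                    "mean_ri": res.mean_ri,
                    "verdict": res.verdict,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ControlDesign:
    mirna_id: str
    arm_3p: str
    arm_5p: str
    positive_control_utr: str
    negative_control_utr: str
    insertion_offset: int
    inserted_positive: str
    inserted_negative: str
    flags: list[str] = field(default_factory=list)


def design_mirna_controls(
    mirna_id: str,
    arm_3p: str,
    arm_5p: str,
    sv40_utr: str,
    insertion_offset: int,
    element_length: int = 22,
) -> ControlDesign:
    """Build positive/negative miRNA control reporter 3'UTRs.

    The positive control inserts the reverse complement of the first
    ``element_length`` nt of the 3p arm into the SV40-derived 3'UTR at
    ``insertion_offset`` (a perfectly complementary target site); the
    negative control does the same with the 5p arm.  RNA input is
    normalized to the DNA alphabet.  Arms shorter than the element length
    are used whole with a ``short arm`` flag.
    """
    if not arm_3p or not arm_5p:
        raise ValueError("both 3p and 5p arm sequences are required")
    if not (0 <= insertion_offset <= len(sv40_utr)):
        raise ValueError(
            f"insertion offset {insertion_offset} outside 3'UTR of length {len(sv40_utr)}"
        )
    flags = []
    elements = {}
    for name, arm in (("3p", arm_3p), ("5p", arm_5p)):
        arm_dna = normalize_dna(arm)
        if set(arm_dna) - set("ACGT"):
            raise ValueError(f"{name} arm contains non-nucleotide characters")
        if len(arm_dna) < element_length:
            flags.append(f"short arm:{name}")
        elements[name] = revcomp(arm_dna[:element_length])
    sv40 = normalize_dna(sv40_utr)
    off = insertion_offset
    return ControlDesign(
        mirna_id=mirna_id,
        arm_3p=normalize_dna(arm_3p),
        arm_5p=normalize_dna(arm_5p),
        positive_control_utr=sv40[:off] + elements["3p"] + sv40[off:],
        negative_control_utr=sv40[:off] + elements["5p"] + sv40[off:],
        insertion_offset=off,
        inserted_positive=elements["3p"],
        inserted_negative=elements["5p"],
        flags=flags,
    )
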