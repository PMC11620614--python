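"""Bundled literature inputs and full-table reproduction.

Two small data files ship with the package:

``table2.tsv``
    Sixteen peptides/polypeptides/proteins with their lengths and reported
    proportions of functional sequences, plus the printed derived columns
    (threshold, biasing-ratio exponent, n_min, sequence identity) so that the
    recomputation can be annotated cell by cell.  Rows where the printed
    value cannot be recovered from the stated formulas carry a
    ``known_discrepancy`` flag naming the offending column(s).

``table3.json``
    Hyper-exponential coefficients (and, for beta-lactamase, the stepwise
    per-mutation tolerance schedule) for the three proteins whose local
    functionality decay has been measured, with lengths and the printed
    threshold / n_max / sequence-identity values.  The raw all-mutation
    beta-lactamase coefficients are a synthetic back-derivation from the
    printed rescaled values and are marked as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .analytic import (
    ProteinRecord,
    ThresholdParams,
    ThresholdReport,
    build_table,
    percolation_threshold,
    round_half_up,
    round_sig,
    sequence_identity,
    format_proportion,
)
from .local_functionality import (
    HyperExponentialModel,
    MutationToleranceSchedule,
    n_max_from_model,
    n_max_from_schedule,
)

__all__ = ["FixtureSet", "LocalModelFixture", "load_fixtures", "reproduce_tables"]


@dataclass(frozen=True)
class LocalModelFixture:
    """One protein's local-functionality model as printed in the literature."""

    name: str
    length: int
    model: HyperExponentialModel
    schedule: MutationToleranceSchedule | None
    printed: dict


@dataclass(frozen=True)
class FixtureSet:
    table2: tuple[ProteinRecord, ...]
    table2_printed: pd.DataFrame
    table3: tuple[LocalModelFixture, ...]
    A_t: float
    nonsynonymous_fraction: float

    def record(self, name: str) -> ProteinRecord:
        for rec in self.table2:
            if rec.name == name:
                return rec
        raise KeyError(name)

    def local_model(self, name: str) -> LocalModelFixture:
        for fx in self.table3:
            if fx.name == name:
                return fx
        raise KeyError(name)


def _data_text(filename: str) -> str:
    return resources.files("seqspace.data").joinpath(filename).read_text()


def load_fixtures() -> FixtureSet:
    """Load the packaged literature fixtures."""
    df = pd.read_csv(
        resources.files("seqspace.data").joinpath("table2.tsv").open("r"),
        sep="\t",
        dtype={"printed_p_th": str, "known_discrepancy": str},
    )
    df["known_discrepancy"] = df["known_discrepancy"].fillna("")
    if len(df) != 16:
        raise ValueError(f"table2 fixture corrupted: expected 16 rows, got {len(df)}")
    records = tuple(
        ProteinRecord(
            name=row["name"],
            L=int(row["length"]),
            p_fs=float(row["p_fs"]),
            source=row["source"],
        )
        for _, row in df.iterrows()
    )

    t3 = json.loads(_data_text("table3.json"))
    fixtures = []
    for name, entry in t3["proteins"].items():
        schedule = (
            MutationToleranceSchedule(entry["schedule"])
            if "schedule" in entry
            else None
        )
        fixtures.append(
            LocalModelFixture(
                name=name,
                length=int(entry["length"]),
                model=HyperExponentialModel(entry["alpha"], entry["beta"]),
                schedule=schedule,
                printed={k: v for k, v in entry.items() if k.startswith("printed_")},
            )
        )
    return FixtureSet(
        table2=records,
        table2_printed=df,
        table3=tuple(fixtures),
        A_t=float(t3["constants"]["A_t"]),
        nonsynonymous_fraction=float(t3["constants"]["nonsynonymous_fraction"]),
    )


def reproduce_tables(fixtures: FixtureSet | None = None) -> dict:
    """Recompute both literature tables and annotate each cell against print.

    Returns a dict with ``table2`` and ``table3`` DataFrames plus a
    ``discrepancies`` list naming every cell where the recomputation differs
    from the printed value.  All differences are confined to the rows flagged
    in the fixture metadata.
    """
    fx = fixtures or load_fixtures()
    params = ThresholdParams(A_t=fx.A_t, n_m=1)
    reports = build_table(list(fx.table2), params)

    rows = []
    discrepancies = []
    printed = fx.table2_printed.set_index("name")
    for rep in reports:
        p = printed.loc[rep.name]
        si_disp = round_half_up(rep.si) if rep.si is not None else None
        row = {
            "name": rep.name,
            "length": rep.L,
            "p_th": rep.p_th_display,
            "p_fs": rep.p_fs,
            "r_b": rep.r_b_display,
            "n_min": rep.n_min,
            "si": f"{si_disp}%",
            "printed_n_min": int(p["printed_n_min"]),
            "flags": p["known_discrepancy"],
        }
        rows.append(row)
        for col, computed, printed_val in [
            ("p_th", rep.p_th_display, p["printed_p_th"]),
            ("r_b", rep.r_b_exponent, int(p["printed_rb_exponent"])),
            ("n_min", rep.n_min, int(p["printed_n_min"])),
            ("si", si_disp, int(p["printed_si"])),
        ]:
            if computed != printed_val:
                discrepancies.append(
                    {
                        "table": 2,
                        "name": rep.name,
                        "column": col,
                        "computed": computed,
                        "printed": printed_val,
                    }
                )
    table2 = pd.DataFrame(rows)

    t3_rows = []
    for fxm in fx.table3:
        p_th = percolation_threshold(fxm.length, fx.A_t, 1)
        n_hyper = n_max_from_model(fxm.model, p_th)
        n_step = (
            n_max_from_schedule(fxm.schedule, p_th) if fxm.schedule is not None else None
        )
        if n_step is not None:
            n_lo, n_hi = sorted((n_step, n_hyper))
            n_max_disp = f"{n_lo}-{n_hi}" if n_lo != n_hi else str(n_lo)
            si_disp = (
                f"{round_half_up(sequence_identity(n_hi, fxm.length), 1)}-"
                f"{round_half_up(sequence_identity(n_lo, fxm.length), 1)}%"
            )
        else:
            n_max_disp = str(n_hyper)
            si_disp = f"{round_half_up(sequence_identity(n_hyper, fxm.length), 1)}%"
        t3_rows.append(
            {
                "name": fxm.name,
                "length": fxm.length,
                "p_th": format_proportion(round_sig(p_th, 2)),
                "n_max": n_max_disp,
                "si": si_disp,
                "n_max_hyperexponential": n_hyper,
                "n_max_stepwise": n_step,
            }
        )
        for col, computed, key in [
            ("p_th", t3_rows[-1]["p_th"], "printed_p_th"),
            ("n_max", n_max_disp, "printed_n_max"),
            ("si", si_disp, "printed_si"),
        ]:
            if key in fxm.printed and computed != fxm.printed[key]:
                discrepancies.append(
                    {
                        "table": 3,
                        "name": fxm.name,
                        "column": col,
                        "computed": computed,
                        "printed": fxm.printed[key],
                    }
                )
    table3 = pd.DataFrame(t3_rows)
    return {"table2": table2, "table3": table3, "discrepancies": discrepancies}
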