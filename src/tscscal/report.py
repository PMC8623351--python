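"""Machine-readable calibration reports and text rendering.

The report captures the content of the graphical rating-light and
rating-details matrices in machine-readable form: a JSON document
(validated against the shipped schema) holding every labeled cell with its
features, the per-electrode amplitude thresholds, the full candidate
ranking, the cost values and both method recommendations — plus a flat CSV
rating table.  ``read_report(write_report(...))`` is lossless for labels,
features and ranks.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .config import ProtocolConfig
from .evaluate import RatingCell, RatingLabel, RatingMatrix, ResponseFeatures
from .pipeline import CalibrationResult
from .recommend import MethodResult, Recommendation
from .validation import validate

SCHEMA_VERSION = 1


def load_schema(name: str = "report") -> dict:
    """Load a shipped JSON schema ('report' or 'truth')."""
    ref = resources.files("tscscal") / "schemas" / f"{name}.schema.json"
    return json.loads(ref.read_text(encoding="utf-8"))


def _method_dict(m: MethodResult) -> dict:
    return {
        "electrode_position": m.electrode_position,
        "threshold_mA": m.threshold_mA,
        "therapy_amplitude_mA": m.therapy_amplitude_mA,
        "reason": m.reason,
    }


def report_dict(
    rating: RatingMatrix,
    rec: Recommendation,
    protocol: Optional[ProtocolConfig] = None,
    noise_profile_uV: Optional[dict] = None,
    quality: Optional[dict] = None,
) -> dict:
    cells = []
    for (m, n, I), cell in sorted(rating.cells.items(), key=lambda kv: (kv[0][1], kv[0][2], kv[0][0])):
        f = cell.features
        cells.append(
            {
                "muscle": m,
                "electrode_position": int(n),
                "amplitude_mA": float(I),
                "label": cell.label.value,
                "color": cell.label.color,
                "amp1_uV": None if f is None else f.amp1_uV,
                "amp2_uV": None if f is None else f.amp2_uV,
                "suppression": None if f is None else f.suppression,
                "reason": cell.reason,
            }
        )
    d = {
        "schema_version": SCHEMA_VERSION,
        "cells": cells,
        "thresholds": [
            {"electrode_position": int(n), "threshold_mA": thr}
            for n, thr in sorted(rec.thresholds.items())
        ],
        "ranking": [
            {
                "rank": e.rank,
                "electrode_position": e.electrode_position,
                "amplitude_mA": e.amplitude_mA,
                "green_count": e.green_count,
            }
            for e in rec.rank_table
        ],
        "costs": [
            {"electrode_position": c.electrode_position, "amplitude_mA": c.amplitude_mA, "J": c.J}
            for c in rec.cost_table
        ],
        "normalizers_uV": dict(rec.normalizers_uV),
        "recommendation": {
            "ranking": _method_dict(rec.ranking),
            "cost": _method_dict(rec.cost),
            "agree": rec.agree,
        },
    }
    if protocol is not None:
        d["protocol"] = protocol.to_dict()
    if noise_profile_uV is not None:
        d["noise_profile_uV"] = dict(noise_profile_uV)
    if quality is not None:
        d["quality"] = quality
    return d


def rating_table(rating: RatingMatrix) -> pd.DataFrame:
    """Flat CSV-ready rating table; invalid cells render as 'invalid'."""
    rows = []
    for (m, n, I), cell in sorted(rating.cells.items(), key=lambda kv: (kv[0][1], kv[0][2], kv[0][0])):
        f = cell.features
        rows.append(
            {
                "muscle": m,
                "electrode_position": n,
                "amplitude_mA": I,
                "label": cell.label.value,
                "color": cell.label.color,
                "amp1_uV": None if f is None else f.amp1_uV,
                "amp2_uV": None if f is None else f.amp2_uV,
                "suppression": None if f is None else f.suppression,
            }
        )
    return pd.DataFrame(rows)


def write_report(
    rating: RatingMatrix,
    rec: Recommendation,
    out_dir,
    protocol: Optional[ProtocolConfig] = None,
    noise_profile_uV: Optional[dict] = None,
    quality: Optional[dict] = None,
) -> tuple[Path, Path]:
    """Write report.json + rating.csv into *out_dir*; returns both paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = report_dict(rating, rec, protocol, noise_profile_uV, quality)
    validate(d, load_schema("report"))
    json_path = out / "report.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2)
    csv_path = out / "rating.csv"
    rating_table(rating).to_csv(csv_path, index=False)
    return json_path, csv_path


def write_result(result: CalibrationResult, out_dir, protocol: Optional[ProtocolConfig] = None):
    """Convenience wrapper serializing a full :class:`CalibrationResult`."""
    quality = {
        "invalid_cell_ratio": result.invalid_cell_ratio,
        "sweep_dispositions": result.disposition_counts(),
    }
    return write_report(
        result.rating,
        result.recommendation,
        out_dir,
        protocol=protocol,
        noise_profile_uV=dict(result.noise.level_uV),
        quality=quality,
    )


def read_report(path) -> dict:
    """Read and schema-validate a report JSON."""
    with open(path, "r", encoding="utf-8") as fh:
        d = json.load(fh)
    validate(d, load_schema("report"))
    return d


def rating_from_report(d: dict) -> RatingMatrix:
    """Reconstruct the rating matrix from a report dict (round-trip)."""
    cells = {}
    muscles: list[str] = []
    for row in d["cells"]:
        m = row["muscle"]
        if m not in muscles:
            muscles.append(m)
        if row["amp1_uV"] is None:
            feats = None
        else:
            feats = ResponseFeatures(
                row["amp1_uV"],
                row["amp2_uV"],
                row["suppression"],
                suppression_defined=row["amp1_uV"] > 0,
            )
        cells[(m, row["electrode_position"], row["amplitude_mA"])] = RatingCell(
            RatingLabel(row["label"]), feats, row.get("reason")
        )
    return RatingMatrix(cells, tuple(muscles))


# -- text rendering ----------------------------------------------------------

_GLYPH = {"gray": ".", "green": "G", "yellow": "Y", "red": "R"}


def render_rating_light(d: dict) -> str:
    """Rating-light matrix as text: one row per amplitude, one column per
    electrode position, four glyphs per cell (muscle order as reported;
    . = no response, G = reflex, Y = M-wave, R = invalid)."""
    cells = d["cells"]
    muscles = list(dict.fromkeys(row["muscle"] for row in cells))
    positions = sorted({row["electrode_position"] for row in cells})
    amplitudes = sorted({row["amplitude_mA"] for row in cells})
    lookup = {(r["muscle"], r["electrode_position"], r["amplitude_mA"]): r["color"] for r in cells}
    best = {(e["electrode_position"], e["amplitude_mA"]) for e in d["ranking"] if e["rank"] == 1}
    lines = [
        "rating light matrix (muscle order: %s)" % ", ".join(muscles),
        "I [mA]  | " + " | ".join(f"n={n:<4d}" for n in positions),
    ]
    for I in amplitudes:
        row = []
        for n in positions:
            glyphs = "".join(_GLYPH.get(lookup.get((m, n, I), " "), " ") for m in muscles)
            row.append(glyphs + ("*" if (n, I) in best else " "))
        lines.append(f"{I:<7g} | " + " | ".join(f"{c:<6s}" for c in row))
    lines.append("(* = best ranked pair)")
    return "\n".join(lines)


def render_details(d: dict, top: int = 5) -> str:
    """Rating-details table: labels, amp1 per muscle, top ranks and J."""
    cells = d["cells"]
    muscles = list(dict.fromkeys(row["muscle"] for row in cells))
    rank_of = {
        (e["electrode_position"], e["amplitude_mA"]): e["rank"]
        for e in d["ranking"]
        if e["rank"] <= top
    }
    j_of = {(c["electrode_position"], c["amplitude_mA"]): c["J"] for c in d["costs"]}
    lookup = {(r["muscle"], r["electrode_position"], r["amplitude_mA"]): r for r in cells}
    pairs = sorted({(r["electrode_position"], r["amplitude_mA"]) for r in cells})
    rows = []
    for n, I in pairs:
        row: dict = {"n": n, "I_mA": I}
        for m in muscles:
            r = lookup.get((m, n, I))
            row[f"{m}"] = "-" if r is None else r["color"]
            row[f"amp1_{m}"] = (
                "" if r is None or r["amp1_uV"] is None else f"{r['amp1_uV']:.1f}"
            )
        row["J"] = f"{j_of.get((n, I), 0.0):.3f}"
        row["rank"] = rank_of.get((n, I), "")
        rows.append(row)
    table = pd.DataFrame(rows).to_string(index=False)

    rec = d["recommendation"]
    lines = [table, ""]
    for method in ("ranking", "cost"):
        m = rec[method]
        if m["electrode_position"] is None:
            lines.append(f"{method:>8s}: no candidate ({m.get('reason')})")
        else:
            lines.append(
                f"{method:>8s}: electrode n={m['electrode_position']}, "
                f"threshold I'={m['threshold_mA']:g} mA, "
                f"therapy amplitude {m['therapy_amplitude_mA']:g} mA"
            )
    if rec["agree"] is not None:
        lines.append("methods %s on the electrode position"
                     % ("agree" if rec["agree"] else "disagree"))
    if not d["ranking"]:
        lines.append("NO CANDIDATE: no pair met the minimal requirement")
    return "\n".join(lines)
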