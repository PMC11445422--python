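"""A/B/I photocycle-state assignment from two hydrogen-bond distances.

A GFP ground-state structure is placed in the A, B or I state from two
structural parameters: d_his, the Nδ1(His148)···Oη(chromophore) distance,
and d_203, the distance from the distal position-203 atom (Oγ1 for Thr,
Cγ2 for Val/Ile) to Oη.  The decision rule operationalises the scatter-plot
regions as hydrogen-bond categories:

* **B** — His148 hydrogen-bonds Oη at normal strength AND position 203
  offers a hydroxyl oxygen hydrogen-bonded to Oη (d_203 ≤ 3.2 Å, O···O);
* **I** — His148 bonds at normal strength but position 203 is NOT
  hydrogen-bonded (a carbon distal atom — C–H···O contacts are weak
  attraction, not hydrogen bonds — or an oxygen beyond 3.2 Å);
* **A** — the His148 bond is weak or absent (d_his > 3.0 Å);
* **unclassified** — d_his below the clash limit (< 2.5 Å).

The state is a pure function of (His148 bond class, position-203 bonding,
distal atom identity); exactly one state per call.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import pandas as pd

from .geometry import (DEFAULT_SCHEME, GeometryReport, HBondStrengthScheme,
                       classify_hbond, measure)
from .structure_io import StructureModel

__all__ = ["StateCall", "IncompleteReportError", "HYDROXYL_BOND_CUTOFF",
           "classify_state", "classify_batch"]

#: O···O distance (Å) below which a hydroxyl at position 203 counts as
#: hydrogen-bonded to the chromophore phenolate
HYDROXYL_BOND_CUTOFF = 3.2


class IncompleteReportError(ValueError):
    """The geometry report lacks one of the two classifying distances."""


@dataclass(frozen=True)
class StateCall:
    structure_id: str
    d_his: float
    d_203: float
    his_class: str
    pos203_bonded: bool
    state: str
    rationale: str
    sigma_his: Optional[float] = None
    sigma_203: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def classify_state(report: GeometryReport,
                   scheme: HBondStrengthScheme = DEFAULT_SCHEME,
                   hydroxyl_cutoff: float = HYDROXYL_BOND_CUTOFF) -> StateCall:
    """Assign A, B, I or unclassified from a geometry report."""
    if report.d_his is None or report.d_203 is None:
        raise IncompleteReportError(
            f"{report.structure_id}: d_his and d_203 both required")
    his_class = classify_hbond(report.d_his, scheme)
    distal_is_oxygen = report.pos203_distal_atom.startswith("O")
    pos203_bonded = distal_is_oxygen and report.d_203 <= hydroxyl_cutoff

    if his_class == "clash":
        state = "unclassified"
        why = f"d_his {report.d_his:.2f} A below the clash limit"
    elif his_class == "normal" and pos203_bonded:
        state = "B"
        why = (f"His148 bond normal ({report.d_his:.2f} A) and position-203 "
               f"hydroxyl bonded ({report.d_203:.2f} A <= {hydroxyl_cutoff} A)")
    elif his_class == "normal":
        state = "I"
        reason = ("carbon distal atom" if not distal_is_oxygen
                  else f"d_203 {report.d_203:.2f} A > {hydroxyl_cutoff} A")
        why = (f"His148 bond normal ({report.d_his:.2f} A) but position 203 "
               f"not hydrogen-bonded ({reason})")
    else:
        state = "A"
        why = f"His148 bond {his_class} (d_his {report.d_his:.2f} A)"

    return StateCall(
        structure_id=report.structure_id,
        d_his=report.d_his,
        d_203=report.d_203,
        his_class=his_class,
        pos203_bonded=pos203_bonded,
        state=state,
        rationale=why,
        sigma_his=report.sigma_his,
        sigma_203=report.sigma_203,
    )


def classify_batch(models: Iterable[StructureModel],
                   scheme: HBondStrengthScheme = DEFAULT_SCHEME,
                   annotate: bool = True):
    """Measure and classify a collection of structures.

    Per-structure failures are recorded and the batch continues.  Returns
    ``(calls, table, failures)`` where ``table`` is the two-axis scatter
    table (d_his, d_203, errors, state) suitable for re-plotting the
    state-comparison figure.
    """
    calls: list = []
    failures: list = []
    for model in models:
        try:
            report = measure(model, scheme)
            if annotate and model.dpi is not None:
                from .error_model import annotate_errors
                annotate_errors(model, report)
            calls.append(classify_state(report, scheme))
        except Exception as exc:  # noqa: BLE001 - batch must survive bad files
            failures.append((getattr(model, "structure_id", "?"), str(exc)))
    table = pd.DataFrame(
        [{"structure_id": c.structure_id, "d_his": c.d_his,
          "sigma_his": c.sigma_his, "d_203": c.d_203,
          "sigma_203": c.sigma_203, "state": c.state,
          "rationale": c.rationale} for c in calls])
    return calls, table, failures
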