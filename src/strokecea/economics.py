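"""Comparative cost-effectiveness statistics: ICER and net monetary benefit."""

from __future__ import annotations

from dataclasses import dataclass

from .engine import ArmOutcome

__all__ = ["CEAResult", "compare"]


@dataclass
class CEAResult:
    """Two-arm comparison (reference minus comparator) at a WTP threshold.

    ``icer`` is ¥ per QALY when ``icer_status == "defined"``; otherwise the
    status flags dominance (``"dominant"``: cheaper and more effective;
    ``"dominated"``: costlier and less effective) or an undefined ratio
    (``"undefined"``: zero QALY difference).
    """

    reference_arm: str
    comparator_arm: str
    reference_cost: float
    comparator_cost: float
    reference_qalys: float
    comparator_qalys: float
    incremental_cost: float
    incremental_qalys: float
    icer: float | None
    icer_status: str
    reference_nmb: float
    comparator_nmb: float
    incremental_nmb: float
    wtp: float

    def to_dict(self) -> dict:
        return {
            "reference_arm": self.reference_arm,
            "comparator_arm": self.comparator_arm,
            "cost": {self.reference_arm: self.reference_cost, self.comparator_arm: self.comparator_cost},
            "qalys": {self.reference_arm: self.reference_qalys, self.comparator_arm: self.comparator_qalys},
            "incremental_cost": self.incremental_cost,
            "incremental_qalys": self.incremental_qalys,
            "icer": self.icer,
            "icer_status": self.icer_status,
            "nmb": {self.reference_arm: self.reference_nmb, self.comparator_arm: self.comparator_nmb},
            "incremental_nmb": self.incremental_nmb,
            "wtp": self.wtp,
        }


def compare(reference: ArmOutcome, comparator: ArmOutcome, wtp: float) -> CEAResult:
    """Incremental cost-effectiveness of ``reference`` versus ``comparator``.

    All statistics are computed from unrounded arm outcomes; NMB is
    ``qalys * wtp - cost``.
    """
    d_cost = reference.discounted_cost - comparator.discounted_cost
    d_qalys = reference.discounted_qalys - comparator.discounted_qalys
    if d_qalys == 0.0:
        icer, status = None, "undefined"
    elif d_qalys > 0 and d_cost < 0:
        icer, status = None, "dominant"
    elif d_qalys < 0 and d_cost > 0:
        icer, status = None, "dominated"
    else:
        icer, status = d_cost / d_qalys, "defined"
    ref_nmb = reference.discounted_qalys * wtp - reference.discounted_cost
    cmp_nmb = comparator.discounted_qalys * wtp - comparator.discounted_cost
    return CEAResult(
        reference_arm=reference.arm,
        comparator_arm=comparator.arm,
        reference_cost=reference.discounted_cost,
        comparator_cost=comparator.discounted_cost,
        reference_qalys=reference.discounted_qalys,
        comparator_qalys=comparator.discounted_qalys,
        incremental_cost=d_cost,
        incremental_qalys=d_qalys,
        icer=icer,
        icer_status=status,
        reference_nmb=ref_nmb,
        comparator_nmb=cmp_nmb,
        incremental_nmb=d_qalys * wtp - d_cost,
        wtp=wtp,
    )
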