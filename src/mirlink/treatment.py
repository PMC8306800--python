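"""Treatment flags and strata.

Chemotherapy exposure is inferred from a claims table: an agent is
attributed to a patient only when at least one claim carries both one of
the agent's procedure codes and a lung-cancer diagnosis code — a claim
with the right procedure code but an unrelated diagnosis does not count.
Surgery/radiation flags come from the registry itself and define four
overlapping analysis strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

STRATUM_LABELS = ("surgery_only", "radiation_only", "surgery_and_radiation", "any_treatment")


@dataclass(frozen=True)
class AgentCodeMap:
    """Agent name -> procedure code set, plus the qualifying diagnosis codes."""

    agent_codes: dict = field(default_factory=dict)
    lung_diagnosis_codes: frozenset = frozenset()

    def __post_init__(self):
        for agent, codes in self.agent_codes.items():
            if not codes:
                raise ValueError(f"empty procedure code set for agent {agent!r}")
        if not self.lung_diagnosis_codes:
            raise ValueError("lung diagnosis code set must be non-empty")

    @property
    def agents(self) -> list[str]:
        return sorted(self.agent_codes)


def default_code_map() -> AgentCodeMap:
    """Synthetic placeholder codes shipped with the simulators.

    HCPCS-like J-codes per agent and ICD-9-like 162.x lung-cancer
    diagnosis codes; real code lists are user-supplied configuration.
    """
    return AgentCodeMap(
        agent_codes={
            "cisplatin": frozenset({"J9060", "J9062"}),
            "carboplatin": frozenset({"J9045"}),
            "paclitaxel": frozenset({"J9265"}),
            "etoposide": frozenset({"J9181", "J9182"}),
        },
        lung_diagnosis_codes=frozenset({"162.2", "162.8", "162.9"}),
    )


def derive_treatment_flags(claims: pd.DataFrame, code_map: AgentCodeMap) -> dict:
    """patient_id -> frozenset of attributed chemo agents.

    Only claims whose procedure code belongs to an agent AND whose
    diagnosis code is a lung-cancer code qualify.  Patients appearing in
    the claims table with no qualifying claim map to the empty set.
    """
    code_to_agent = {}
    for agent, codes in code_map.agent_codes.items():
        for c in codes:
            code_to_agent[c] = agent
    flags: dict = {pid: set() for pid in claims["patient_id"].unique()}
    qualifying = claims[claims["diagnosis_code"].isin(code_map.lung_diagnosis_codes)]
    for pid, proc in zip(qualifying["patient_id"], qualifying["procedure_code"]):
        agent = code_to_agent.get(proc)
        if agent is not None:
            flags[pid].add(agent)
    return {pid: frozenset(s) for pid, s in flags.items()}


def stratify_treatment(registry: pd.DataFrame) -> dict:
    """Partition-free treatment strata as boolean masks over the registry.

    surgery_only: any surgery without preoperative radiation;
    radiation_only: any radiation without surgery;
    surgery_and_radiation: both modalities;
    any_treatment: any of surgery, radiation, or chemotherapy.
    The strata are analysis views and deliberately overlap.
    """
    surgery = registry["surgery"].astype(bool)
    radiation = registry["radiation"].astype(bool)
    preop = registry["preop_radiation"].astype(bool)
    chemo = registry["chemo_agents"].map(bool)
    return {
        "surgery_only": surgery & ~preop,
        "radiation_only": radiation & ~surgery,
        "surgery_and_radiation": surgery & radiation,
        "any_treatment": surgery | radiation | chemo,
    }


def chemo_subset(registry: pd.DataFrame, agent: str) -> pd.Series:
    """Boolean mask selecting patients by chemotherapy exposure.

    ``"none"`` selects patients with no attributed agent (the prognostic
    analysis population), ``"any"`` selects patients with at least one,
    and a specific agent name selects patients whose set contains it.
    """
    sets = registry["chemo_agents"]
    if agent == "none":
        return sets.map(lambda s: len(s) == 0)
    if agent == "any":
        return sets.map(bool)
    known = set().union(*sets) if len(sets) else set()
    if agent not in known and agent not in default_code_map().agents:
        raise KeyError(f"unknown chemotherapy agent {agent!r}")
    return sets.map(lambda s: agent in s)
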