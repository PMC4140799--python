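"""Reference colony summaries bundled with the package.

Worker-sample summaries for ten colonies of five Neotropical army ant
species from Chiapas, Mexico (Eciton mexicanum, E. vagans, Labidus
coecus, L. praedator and Nomamyrmex esenbeckii): the number of
genotyped workers retained for paternity deduction (n), the observed
patriline count (k_obs) and the reported effective paternity (m_e).
These summaries serve as worked-example inputs for the estimators —
k_est and the species-level summaries are recomputed from them, not
stored.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ColonyRecord", "CHIAPAS_COLONIES"]


@dataclass(frozen=True)
class ColonyRecord:
    colony_id: str
    species_id: str
    location: str
    n: int
    k_obs: int
    m_e: float


CHIAPAS_COLONIES: tuple[ColonyRecord, ...] = (
    ColonyRecord("Em1", "E_mexicanum", "Cacahoatan", 115, 18, 15.07),
    ColonyRecord("Em2", "E_mexicanum", "Cacahoatan", 125, 12, 10.32),
    ColonyRecord("Em3", "E_mexicanum", "Tuxtla_Chico", 154, 20, 18.02),
    ColonyRecord("Ev1", "E_vagans", "Tuxtla_Chico", 94, 22, 19.18),
    ColonyRecord("Lc1", "L_coecus", "Tapachula", 93, 11, 8.10),
    ColonyRecord("Lp1", "L_praedator", "Cacahoatan", 104, 26, 25.51),
    ColonyRecord("Lp2", "L_praedator", "Tapachula", 108, 18, 15.58),
    ColonyRecord("Lp3", "L_praedator", "Tuxtla_Chico", 79, 26, 22.33),
    ColonyRecord("Ne1", "N_esenbeckii", "Cacahoatan", 8, 5, 5.76),
    ColonyRecord("Ne2", "N_esenbeckii", "Tapachula", 80, 7, 6.01),
)
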