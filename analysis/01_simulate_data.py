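"""Simulate the two experiments: the 5-genotype full diallel and the
F1/F2 inheritance design.

Ground truth mirrors the qualitative structure reported for Tetranychus
urticae: CI penetrance (theta) is driven by the male genotype — near
complete for Beis males, intermediate for LonX/Scp, weak for Stt/Temp —
with one strong male x female interaction (Beis male x LonX female
reduced); the CI phenotype is mostly female mortality (phi small) except
for LonX females mated to Scp males, where a recessive maternal modifier
diverts CI-affected eggs into male development (phi high).

Writes results/data/diallel.csv and results/data/inheritance.csv.
"""

from pathlib import Path

from haploci import (
    DiallelSimParams,
    InheritanceSimParams,
    simulate_diallel,
    simulate_inheritance,
    write_records,
)
from haploci.synthetic_data import DEFAULT_PANEL

OUT = Path(__file__).resolve().parent.parent / "results" / "data"

MALE_THETA = {"Beis": 0.95, "LonX": 0.55, "Scp": 0.6, "Stt": 0.2, "Temp": 0.15}
THETA_INTERACTIONS = {("Beis", "LonX"): 0.75}
PHI_HIGH_CELLS = {("Scp", "LonX"): 0.75}  # (male, female): LonX maternal effect
PHI_BASE = 0.05


def main() -> None:
    labels = [g.label for g in DEFAULT_PANEL]
    theta = {
        (m, f): THETA_INTERACTIONS.get((m, f), MALE_THETA[m])
        for m in labels for f in labels
    }
    phi = {
        (m, f): PHI_HIGH_CELLS.get((m, f), PHI_BASE)
        for m in labels for f in labels
    }
    diallel = simulate_diallel(DiallelSimParams(theta=theta, phi=phi, seed=1))
    inheritance = simulate_inheritance(
        InheritanceSimParams(k_loci=1, phi_high=0.75, phi_low=PHI_BASE,
                             theta=0.6, n_f2=30, seed=1)
    )
    OUT.mkdir(parents=True, exist_ok=True)
    write_records(diallel, OUT / "diallel.csv")
    write_records(inheritance, OUT / "inheritance.csv")
    print(f"diallel: {len(diallel)} broods over "
          f"{len({r.cross_type.pair + (r.cross_type.male_infected,) for r in diallel})} "
          f"cross types -> {OUT / 'diallel.csv'}")
    print(f"inheritance: {len(inheritance)} single-female broods "
          f"-> {OUT / 'inheritance.csv'}")


if __name__ == "__main__":
    main()
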