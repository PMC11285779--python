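"""Generate the working assemblage table.

Simulates the default two-formation assemblage (47 specimens: six clades
nested in six feeding guilds, 25 OCF / 22 KCF) and writes it to
results/specimens.csv. Swap in a real measurement table with the same CSV
schema to run the downstream steps on published data instead.
"""

import json
from pathlib import Path

from jawmorph import (SimulationConfig, simulate_assemblage,
                      summarize_composition, write_specimen_table)

SEED = 20240515
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = simulate_assemblage(SimulationConfig(seed=SEED))
    write_specimen_table(table, OUT / "specimens.csv")
    comp = summarize_composition(table)
    print(f"wrote {len(table)} specimens to {OUT / 'specimens.csv'}")
    print(json.dumps(comp, indent=2))


if __name__ == "__main__":
    main()
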