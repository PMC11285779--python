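"""Compute the biomechanical character matrix.

Derives the 11 morphofunctional characters (plus ltMA and ML) for every
specimen, z-corrects them, and writes both matrices. The standardized matrix
is the input to the morphospace and every inferential test.
"""

import json
from pathlib import Path

from jawmorph import read_specimen_table, character_table, standardized_characters

OUT = Path("results")


def main() -> None:
    table = read_specimen_table(OUT / "specimens.csv")
    chars = character_table(table)
    chars.to_csv(OUT / "characters.csv", index_label="specimen_id")
    std = standardized_characters(table)
    std.values.to_csv(OUT / "characters_standardized.csv",
                      index_label="specimen_id")
    (OUT / "standardization.json").write_text(json.dumps({
        "column_means": std.column_means.to_dict(),
        "column_sds": std.column_sds.to_dict()}, indent=2))
    print(f"characters for {len(chars)} specimens; "
          f"mean aMA = {chars['aMA'].mean():.3f}, "
          f"mean oMA = {chars['oMA'].mean():.3f}")


if __name__ == "__main__":
    main()
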