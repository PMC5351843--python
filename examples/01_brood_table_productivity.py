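"""Read a brood table and compute log-productivity.

Builds a tiny spawner/recruit table for one population, reads it back through
the validating loader, and prints log(R/S) per brood year — the response
variable every stock-recruit model in this package consumes.
"""

import tempfile
from pathlib import Path

import prodshift as ps

csv = """population,brood_year,spawners,recruits
pws,1981,100,250
pws,1982,200,100
pws,1983,300,300
pws,1984,150,0
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "brood.csv"
    path.write_text(csv)
    table = ps.read_brood_table(path)
    series = ps.compute_productivity(table)[0]

print(f"population: {series.population_id}")
print(series.data.round(4))
print(
    "\nlog_rs > 0 means the cohort more than replaced its parents; the 1984\n"
    "row (zero recruits) is excluded because log(0) is undefined."
)
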