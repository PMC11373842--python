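# foodprint

A biophysical simulation model, as a tested Python library + CLI, that
converts diet patterns (population-level per-capita servings or
individual-level survey records over 22 food groups) backwards through the
food system into agricultural commodity requirements and then into land,
fertilizer-nutrient, pesticide, and irrigation-water use — with open/closed
trade, multiuse-crop coproduct correction, grazing-land reallocation, and
carrying-capacity estimation.

## Layout

| module | role |
|---|---|
| `foodprint.food_system_data` | parameter tables (foods, dairy, fats/oils, feed, aquaculture, trade, yields, amendments, land base, nutrients): load / validate / write, delimited format + manifest |
| `foodprint.diet_input` | food-group vectors, survey records, analytic exclusion rules (age, reliability, zero intake, 3-SD resource outliers), population means |
| `foodprint.commodity_flow` | preference reapportionment, serving/loss-waste/processing conversion, fluid-milk limiting fraction, fat/oil decomposition |
| `foodprint.feed_trade` | livestock feed coefficients, aquaculture corn/soymeal nutritional solve, trade balances |
| `foodprint.land_engine` | 8-step multiuse-crop coproduct ledger, per-food land by land type |
| `foodprint.capacity_engine` | land availability, grazing reallocation, population fed / carrying capacity, total land, amendment use, nutrient summary |
| `foodprint.synthetic_fixtures` | deterministic MINI toy food system + seeded right-skewed synthetic surveys |
| `foodprint.batch_cli` | `run_single` / `run_batch` pipelines and the `foodprint` CLI |

Internal units follow the source model (lb, acres, servings/day); SI
conversion (ha, kg, m³) happens only at the report layer.

## CLI

```sh
# write the MINI parameter directory and a seeded synthetic survey
foodprint fixture --seed 1 --n 200 --out scratch/fx

# validate any parameter directory
foodprint validate --params scratch/fx/params

# one diet end-to-end (defaults to the MINI reference diet)
foodprint run --params scratch/fx/params --population 100 \
    --trade closed --units si --out scratch/run

# survey batch: exclusions, per-record totals, weighted summary
foodprint batch --params scratch/fx/params --survey scratch/fx/survey.tsv \
    --population 100 --out scratch/batch
```

Outputs: `expanded.tsv` (per food × land type × amendment), `summary.json`
for single runs; `totals.tsv` (per participant), `summary.tsv`,
`exclusions.tsv` for batches. Scenario toggles: `--trade open|closed`,
`--no-aquatic` (drop the aquaculture feed pathway), `--loss-waste-variant`
(alternate loss/waste columns), `--aquaculture-mode` and `--trade-sign`
(strict reproductions of the source model's printed equation forms).

## Diet survey input contract

One row per participant: `participant_id`, `age_years`, `survey_weight`,
optional `survey_cycle`, `recall_reliable`, `energy_kcal`, plus one column
per food group in the group's serving unit (cup-eq, oz-eq, or teaspoons).
Conversion from raw recall food codes to group servings is upstream of this
package. Column names are remappable via a YAML schema
(`foodprint.diet_input.load_schema`).
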