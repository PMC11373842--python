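# MINI reference worksheet (hand-computed oracle)

This document walks the MINI toy food system's reference diet through every
model stage with plain arithmetic. `tests/mini_oracle.py` transliterates the
same arithmetic (importing nothing from the package) and the acceptance suite
compares pipeline output against it to 1e-9 relative.

Constants: 454 g/lb, 365 d/yr, fluid-milk solids 0.037 (fat) and 0.086
(non-fat).

## Reference diet (servings/day)

grains 2, other vegetables 1, starchy vegetables 1, fruit 1, fluid milk 1,
cheese 1, beef 3, chicken 2, aquatic food 1, plant oils 3, lard/tallow 1,
sweeteners 4.

## 1. Food requirements (lb commodity/person/yr)

`mass = servings x serving_g/454 x preference x loss_waste x processing x 365`

| food | calc | lb/yr |
|---|---|---|
| bread (wheat) | 2 x 28/454 x 1.0* x 1.25 x 1.37 x 365 | 77.1003 |
| carrot | 1 x 120/454 x 1.5 x 1.1 x 365 | 159.1960 |
| potato | 1 x 160/454 x 1.6 x 365 | 205.8150 |
| apple | 1 x 150/454 x 1.4 x 1.2 x 365 | 202.5991 |
| beef (cattle) | 3 x 28/454 x 1.3 x 1.5 x 365 | 131.6895 |
| chicken (broilers) | 2 x 28/454 x 1.25 x 1.4 x 365 | 78.7885 |
| salmon edible | 1 x 28/454 x 1.2 x 365 | 27.0132 → farmed 13.5066, wild 13.5066 |
| cooking oil | 3 x 4.5/454 x 1.15 x 365 | 12.4816 → soy oil 7.4889, corn oil 4.9926 |
| lard | 1 x 4/454 x 1.1 x 365 | 3.5374 |
| corn syrup (corn) | 4 x 5/454 x 1.1 x 1.6 x 365 | 28.2996 |

*bread's raw preference 0.8 reapportions to 1.0 because tortilla is
non-producible.

## 2. Dairy limiting fraction

Pre-processing masses: milk 1 x 245/454 x 1.1 x 365 = 216.6685; cheese
1 x 42/454 x 1.2 x 365 = 40.5251.

- FM_fat = 216.6685x0.037/0.037 + 40.5251x0.30/0.037 = 216.6685 + 328.5391 = 545.2076
- FM_nonfat = 216.6685 + 40.5251x0.25/0.086 = 334.4587
- FM = max = **545.2076** (fat-limited); fluid-milk processing conversion 1.0.

## 3. Aquaculture solve (salmon)

feed/edible = FCR/efficiency = 1.0/0.5 = 2; energy req = 2x1.55 = 3.1;
protein req = 2x0.285 = 0.57. Solve 1.6c+1.5s=3.1, 0.09c+0.48s=0.57 →
**corn 1.0, soymeal 1.0** lb per lb edible.

## 4. Feed demands (lb/person/yr)

- cattle 131.6895: forage x6 = 790.137, corn x2 = 263.379, hay x1 = 131.6895
- broilers 78.7885: corn x2 = 157.577, soymeal x1 = 78.7885
- fluid milk 545.2076: hay x0.5 = 272.604, forage x0.3 = 163.562, corn x0.2 = 109.042
- farmed salmon 13.5066: corn 13.5066, soymeal 13.5066

## 5. Multiuse ledger (steps 1–8)

1. corn for sweeteners 28.2996 → corn oil coproduced x0.04 = 1.13198;
   gluten-feed protein x0.25x0.20 = 1.41498
2. soybeans for soy oil = 7.4889/0.2 = 37.4447
3. soy meal protein = 37.4447x0.8x0.48 = 14.3787; lard/tallow coproduced =
   131.6895x0.04 + 78.7885x0.02 = 6.84335
4. corn oil spared = min(4.9926, 1.13198) = 1.13198; corn spared = /0.04 = 28.2996
5. lard remaining = max(0, 3.5374 − 6.84335) = 0
6. surplus fats = (1.13198−1.13198) + (6.84335−3.5374) = 3.30590;
   displaced soy oil = min(7.4889, 3.30590) = 3.30590;
   soybeans spared = /0.2 = 16.5295
7. net soy crush = 37.4447 − 16.5295 = 20.9151; feed protein = 1.41498 +
   20.9151x0.8x0.48 = 9.44639
8. soymeal feed demand = 78.7885+13.5066 = 92.2951; displaced meal =
   min(92.2951, 9.44639/0.48) = 19.6800; soybeans spared = /0.8 = 24.6000

## 6. Land (acres/person/yr)

- wheat 77.1003/2700 = 0.0285557
- carrot 159.1960/30000 = 0.0053065
- potato 205.8150/40000 = 0.0051454
- apple 202.5991/25000 = 0.0081040
- corn: (28.2996 + 263.379 + 157.577 + 109.042 + 13.5066 + (4.9926−1.13198)/0.04) / 9000
  = 668.320/9000 = 0.0742578
- soybeans: ((7.4889−3.30590)/0.2 + (92.2951−19.6800)/0.8) / 3000
  = (20.9151 + 90.7689)/3000 = 0.0372280
- hay: (131.6895+272.604)/5000 = 0.0808586 (cropland pasture)
- grazed forage: (790.137+163.562)/2000 = 0.4768494 (permanent pasture)

Cultivated total 0.1585969; forage 0.0808586; grazing 0.4768494.

## 7. Availability, grazing adjustment, output (population 100)

- cropping intensity = 120/100 = 1.2; productive = 150+50 = 200;
  proportion cultivated = 120/200 = 0.6;
  available cultivated food cropland = 200x0.6/1.2 − 10 = 90;
  all-uses food cropland = 200 − 10 = 190; grazing = 800+200 = 1000.
- RA = 1000/190 = 5.2632; RY = 4000/2000 = 2 (cropland grazing yield over
  grazing-land yield); crop side = 0.1585969/1.2 + 0.0808586 = 0.2130394;
  RR = 0.4768494/0.2130394 = 2.2383 ≤ RA → no reallocation.
- Population fed: 90/0.1585969 = 567.48; 190/0.2130394 = 891.92;
  1190/(0.2130394+0.4768494) = 1724.96. Carrying capacity = 567.48/100 =
  **5.6748**.
- Total land = (0.2130394 + 0.4768494) x 100 = **68.9872 acres**.

## 8. Amendments (per capita, rate x raw acres; apple has no rates → 0)

e.g. N = 0.0285557x60 + 0.0742578x140 + 0.0372280x20 + 0.0053065x100 +
0.0051454x180 + 0.0808586x40 = 17.5451 lb. Other amendments analogous.

## 9. Nutrients (per capita/day)

Energy = 2x80 + 1x50 + 1x130 + 1x95 + 1x150 + 1x170 + 3x70 + 2x50 + 1x60 +
3x40 + 1x36 + 4x15 = 1341 kcal; protein/fat/carbohydrate analogous.
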