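# Default CRECE-shaped instrument configuration.
#
# This is a documented RECONSTRUCTION of the published instrument's
# structure, not the original questionnaire: the tool has 22 items in four
# sections — food security (2), food habits (4), food intake (11), food
# behavior (5) — with total scores 0-48 banded as low 0-15, moderate 16-29,
# high 30-48.  The per-item response labels and point maps below are a
# plausible shape whose per-item maxima sum exactly to 48; the original
# item wording and point values are not published.  Higher points = higher
# risk on every item.
name: crece-default
sections:
  - {name: food_security, items: 2}
  - {name: food_habits, items: 4}
  - {name: food_intake, items: 11}
  - {name: food_behavior, items: 5}
cutoffs:
  low_max: 15
  moderate_max: 29
  instrument_max: 48
items:
  # Food security: the two household food-insecurity statements.
  - id: FS1
    section: food_security
    scores: {never true: 0, sometimes true: 1, often true: 2}
  - id: FS2
    section: food_security
    scores: {never true: 0, sometimes true: 1, often true: 2}
  # Food habits: mealtime and preparation patterns (0-2 each).
  - id: FH1
    section: food_habits
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FH2
    section: food_habits
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FH3
    section: food_habits
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FH4
    section: food_habits
    scores: {never: 0, sometimes: 1, often: 2}
  # Food intake: frequency of intake of food groups and risk foods (0-2 each).
  - id: FI1
    section: food_intake
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FI2
    section: food_intake
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FI3
    section: food_intake
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FI4
    section: food_intake
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FI5
    section: food_intake
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FI6
    section: food_intake
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FI7
    section: food_intake
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FI8
    section: food_intake
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FI9
    section: food_intake
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FI10
    section: food_intake
    scores: {never: 0, sometimes: 1, often: 2}
  - id: FI11
    section: food_intake
    scores: {never: 0, sometimes: 1, often: 2}
  # Food behavior: screen time, sleep, pickiness, mealtime battles (four
  # 0-3 items and one 0-2 item).
  - id: FB1
    section: food_behavior
    scores: {never: 0, rarely: 1, sometimes: 2, often: 3}
  - id: FB2
    section: food_behavior
    scores: {never: 0, rarely: 1, sometimes: 2, often: 3}
  - id: FB3
    section: food_behavior
    scores: {never: 0, rarely: 1, sometimes: 2, often: 3}
  - id: FB4
    section: food_behavior
    scores: {never: 0, rarely: 1, sometimes: 2, often: 3}
  - id: FB5
    section: food_behavior
    scores: {never: 0, sometimes: 1, often: 2}
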