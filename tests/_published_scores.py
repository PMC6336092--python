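"""The published four-flat score table: 12 services x 4 sites of "I/S%" cells.

Used only for internal-consistency checks of the score algebra (the raw
survey indicators behind these numbers are not reproducible at desk scale).
``–`` marks cells omitted from the original analysis.
"""

SITES = ["SN", "UK", "TR", "OR"]

PUBLISHED_MATRIX = {
    "food_provision":        ["12.4/-41%", "5.3/+17%", "4.0/+1%", "5.6/+12%"],
    "coastal_protection":    ["81.2/0%", "96.4/+13%", "85.1/-4%", "94.3/+4%"],
    "recreation":            ["–/–", "78.7/-1%", "0.3/-7%", "0.3/+16%"],
    "environmental_education": ["40.3/-41%", "66.8/+11%", "0.0/–", "39.4/+17%"],
    "research":              ["64.7/+26%", "14.5/+2%", "75.1/+34%", "70.8/+48%"],
    "historical_sites":      ["–/–", "–/–", "50.8/+3%", "80.0/+13%"],
    "rest_and_relaxation":   ["–/–", "100/+10%", "3.2/-3%", "2.8/+17%"],
    "suspended_removal":     ["100/+18%", "20.7/+13%", "14.3/+9%", "8.9/+10%"],
    "organic_decomposition": ["52.1/-8%", "12.0/+27%", "40.2/+22%", "17.8/+19%"],
    "carbon_storage":        ["58.7/-9%", "16.6/-3%", "79.7/-8%", "13.6/+3%"],
    "degree_of_diversity":   ["86.5/+10%", "100/+28%", "87.9/-2%", "78.1/+2%"],
    "rare_species":          ["7.8/-14%", "12.0/+16%", "100/+54%", "100/+31%"],
}
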