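{
  "noun": {
    "maple": ["birch", "aspen"],
    "birch": ["maple", "aspen"],
    "aspen": ["maple", "birch"],
    "falcon": ["hawk", "kestrel"],
    "hawk": ["falcon", "kestrel"],
    "kestrel": ["falcon", "hawk"],
    "copper": ["bronze", "brass"],
    "bronze": ["copper", "brass"],
    "brass": ["copper", "bronze"],
    "violin": ["fiddle", "viola"],
    "fiddle": ["violin", "viola"],
    "viola": ["violin", "fiddle"],
    "glacier": ["iceberg", "floe"],
    "iceberg": ["glacier", "floe"],
    "floe": ["glacier", "iceberg"],
    "sonnet": ["haiku", "limerick"],
    "haiku": ["sonnet", "limerick"],
    "limerick": ["sonnet", "haiku"],
    "cedar": ["spruce", "juniper"],
    "spruce": ["cedar", "juniper"],
    "juniper": ["cedar", "spruce"],
    "heron": ["egret", "crane"],
    "egret": ["heron", "crane"],
    "crane": ["heron", "egret"],
    "cobalt": ["indigo", "azure"],
    "indigo": ["cobalt", "azure"],
    "azure": ["cobalt", "indigo"],
    "trumpet": ["cornet", "bugle"],
    "cornet": ["trumpet", "bugle"],
    "bugle": ["trumpet", "cornet"],
    "canyon": ["ravine", "gorge"],
    "ravine": ["canyon", "gorge"],
    "gorge": ["canyon", "ravine"],
    "ballad": ["anthem", "chorus"],
    "anthem": ["ballad", "chorus"],
    "chorus": ["ballad", "anthem"],
    "willow": ["poplar", "sycamore"],
    "poplar": ["willow", "sycamore"],
    "sycamore": ["willow", "poplar"],
    "sparrow": ["finch", "wren"],
    "finch": ["sparrow", "wren"],
    "wren": ["sparrow", "finch"],
    "crimson": ["scarlet", "vermilion"],
    "scarlet": ["crimson", "vermilion"],
    "vermilion": ["crimson", "scarlet"],
    "flute": ["piccolo", "fife"],
    "piccolo": ["flute", "fife"],
    "fife": ["flute", "piccolo"],
    "lagoon": ["estuary", "inlet"],
    "estuary": ["lagoon", "inlet"],
    "inlet": ["lagoon", "estuary"],
    "fable": ["parable", "allegory"],
    "parable": ["fable", "allegory"],
    "allegory": ["fable", "parable"],
    "cypress": ["sequoia", "redwood"],
    "sequoia": ["cypress", "redwood"],
    "redwood": ["cypress", "sequoia"],
    "pelican": ["gannet", "cormorant"],
    "gannet": ["pelican", "cormorant"],
    "cormorant": ["pelican", "gannet"],
    "amber": ["ochre", "sienna"],
    "ochre": ["amber", "sienna"],
    "sienna": ["amber", "ochre"],
    "cello": ["contrabass", "doublebass"],
    "contrabass": ["cello", "doublebass"],
    "doublebass": ["cello", "contrabass"],
    "mesa": ["plateau", "butte"],
    "plateau": ["mesa", "butte"],
    "butte": ["mesa", "plateau"],
    "riddle": ["proverb", "maxim"],
    "proverb": ["riddle", "maxim"],
    "maxim": ["riddle", "proverb"],
    "wife": ["spouse", "partner", "better half"],
    "spouse": ["partner", "wife", "better half"],
    "husband": ["spouse", "partner", "better half"],
    "home": ["house", "residence"],
    "house": ["home", "residence"],
    "friend": ["pal", "buddy", "companion"],
    "pal": ["friend", "buddy", "companion"],
    "buddy": ["friend", "pal", "companion"],
    "work": ["job", "employment"],
    "job": ["work", "employment"],
    "food": ["meal", "fare"],
    "meal": ["food", "fare"]
  },
  "verb": {
    "love": ["adore", "cherish"],
    "adore": ["love", "cherish"],
    "like": ["enjoy", "fancy"],
    "enjoy": ["like", "fancy"],
    "think": ["believe", "reckon"],
    "believe": ["think", "reckon"],
    "start": ["begin", "commence"],
    "begin": ["start", "commence"],
    "talk": ["speak", "chat"],
    "speak": ["talk", "chat"],
    "walk": ["stroll", "amble"],
    "stroll": ["walk", "amble"]
  }
}
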