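{
 "odor_thresholds.csv": "43ae0c4a307e73d6a0c3508be5c5715c08da030377235f3b6eca7b520203cea8",
 "printed_class_totals.csv": "27c0eb22e0e5acad09416ff690da61b6e907cb2b648e5badb353273788ff8c57",
 "printed_roav.csv": "e19bd13e5426b38e6541479d32df0f4c0caf87f588293866bac1aaf638dc81cc",
 "wine_panel_concentrations.csv": "dee6daf4bb56972ccb07654d5ba80259598b316302a6b678b9fad99775a1d4d6"
}
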