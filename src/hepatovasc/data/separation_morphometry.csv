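stage,mouse,separation,density,radius_um,tortuosity
normal,1,unseparated,0.0956,2.4781,0.5573
normal,1,separated,0.0941,3.2731,0.5375
normal,2,unseparated,0.0961,2.5345,0.5495
normal,2,separated,0.0945,3.2699,0.5313
normal,3,unseparated,0.0953,2.4063,0.5534
normal,3,separated,0.0938,3.1215,0.5349
early,1,unseparated,0.1078,2.5064,0.5519
early,1,separated,0.0552,2.6495,0.4822
early,2,unseparated,0.0931,2.5129,0.5791
early,2,separated,0.0541,2.6995,0.4978
early,3,unseparated,0.1005,2.5097,0.5455
early,3,separated,0.0515,2.6345,0.4884
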