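sample_id,DCC,PDZD2,LRRFIP1
NE 2TC,3.853506079,0.026305316,25.55396049
NE CT1,2.887782327,0.012957265,14.26667269
NE MTT,1.019851667,0.032658206,30.08928667
PIT,2.030313016,0.025800759,3.645085529
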