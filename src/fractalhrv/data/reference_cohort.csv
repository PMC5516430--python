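index,subject,Pre,F01,F02,F03,Post
beta,Case1,-1.078,-0.899,-0.690,-0.798,-0.985
beta,Case2,-1.155,-1.093,-0.835,-0.964,-1.101
beta,Case3,-1.287,-1.206,-1.039,-1.099,-1.245
beta,Case4,-1.183,-0.967,-1.097,-0.889,-1.161
beta,Case5,-1.278,-0.904,-0.829,-0.880,-1.490
beta,Case6,-1.030,-1.130,-0.838,-0.845,-1.077
beta,Case7,-1.082,-0.842,-1.096,-0.980,-1.132
ulf,Case1,1394.5,1392.1,795.3,2140.0,1643.7
ulf,Case2,3617.1,2575.8,1199.0,2473.1,3545.4
ulf,Case3,3152.5,3650.0,2140.9,2743.5,3811.4
ulf,Case4,3219.9,3949.0,2328.3,1801.6,3001.1
ulf,Case5,2520.2,1065.5,1534.0,1626.8,3542.7
ulf,Case6,6363.2,6975.8,2824.9,3697.7,4898.3
ulf,Case7,9936.1,3940.7,6054.5,7242.4,7922.4
vlf,Case1,937.1,1174.8,1242.1,1158.4,1372.8
vlf,Case2,1421.7,965.7,1176.0,1576.0,2089.7
vlf,Case3,1257.0,1118.1,1103.3,1247.4,1618.8
vlf,Case4,1635.0,2204.9,1103.2,1385.4,1569.4
vlf,Case5,715.0,761.2,753.0,760.8,652.5
vlf,Case6,4054.7,2494.8,2978.1,3177.0,2920.2
vlf,Case7,5276.2,3312.4,2376.0,3810.3,3936.7
lf,Case1,573.80,374.15,360.89,323.51,498.64
lf,Case2,537.50,537.80,646.60,823.50,848.10
lf,Case3,653.00,535.10,482.12,571.80,636.26
lf,Case4,753.50,1190.60,851.40,980.10,758.80
lf,Case5,157.86,135.99,203.03,177.68,137.86
lf,Case6,1341.30,1052.90,1173.20,1142.60,1000.60
lf,Case7,866.10,745.90,570.90,672.30,800.00
hf,Case1,107.16,85.90,70.90,171.49,92.04
hf,Case2,113.62,90.92,98.68,127.72,192.28
hf,Case3,52.18,55.91,73.52,69.54,99.84
hf,Case4,163.19,233.26,157.51,220.87,154.62
hf,Case5,37.62,21.79,31.22,30.29,23.64
hf,Case6,192.85,147.03,178.46,192.50,114.60
hf,Case7,164.67,157.70,100.44,119.11,137.34
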